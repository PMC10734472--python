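import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from fgislands.ecostats import (
    StatResult,
    VersionAbundanceMatrix,
    correlate_versions_with_environment,
    diagnostic_sequences,
    kruskal_wallis,
    spearman,
    version_abundance,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_wilcoxon(diffs):
    """Literal enumeration of all 2^n sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    t_obs = min(w_plus, w_minus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= t_obs + 1e-9:
            count += 1
    return t_obs, min(1.0, 2.0 * count / 2**n)


def brute_force_spearman_p(x, y):
    """Exact two-sided p by enumerating every rank permutation."""
    rx, ry = rankdata(x), rankdata(y)

    def rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return (a * b).sum() / math.sqrt((a * a).sum() * (b * b).sum())

    obs = abs(rho(rx, ry))
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho(rx, np.asarray(perm))) >= obs - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_eight_pairs_single_minimal_discordant(self):
        # seven positive differences, one negative with the smallest |d|
        diffs = [-1, 2, 3, 4, 5, 6, 7, 8]
        res = wilcoxon_signed_rank(diffs)
        assert res.statistic == 1.0
        assert res.p_value == pytest.approx(0.015625)
        assert f"{res.p_value:.3f}" == "0.016"

    def test_eight_pairs_all_positive(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6, 7, 8])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.0078125)  # 2/256

    def test_exact_p_n8_t1_is_one_sixty_fourth(self):
        res = wilcoxon_signed_rank([-1, 2, 3, 4, 5, 6, 7, 8])
        assert res.p_value == pytest.approx(1 / 64)

    def test_all_zero_differences_na(self):
        res = wilcoxon_signed_rank([1, 2], [1, 2])
        assert res.statistic is None and res.p_value is None
        assert "zero" in res.status

    def test_paired_interface_matches_difference_interface(self):
        x = [5.0, 7.0, 3.0, 9.0]
        y = [4.0, 9.0, 1.0, 2.0]
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank(np.subtract(x, y))
        assert a.statistic == b.statistic and a.p_value == b.p_value

    def test_matches_brute_force_enumeration_many_fixtures(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(2, 11))
            diffs = rng.integers(-20, 21, size=n)
            if not np.any(diffs != 0):
                continue
            t_oracle, p_oracle = brute_force_wilcoxon(diffs)
            res = wilcoxon_signed_rank(diffs.astype(float))
            assert res.statistic == pytest.approx(t_oracle)
            assert res.p_value == pytest.approx(p_oracle)

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(7)
        for _ in range(20):
            d = rng.permutation(np.arange(1, 11)) * rng.choice([-1, 1], size=10)
            res = wilcoxon_signed_rank(d.astype(float))
            ref = scipy_wilcoxon(d, mode="exact")
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.5, 1.0, size=60)
        res = wilcoxon_signed_rank(d)
        assert res.method == "normal-approx"
        assert 0 <= res.p_value <= 1


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_increasing_rho_one(self):
        res = spearman([1, 2, 3, 4, 5], [10, 20, 25, 40, 100])
        assert res.statistic == pytest.approx(1.0)

    def test_monotone_decreasing_rho_minus_one(self):
        res = spearman([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert res.statistic == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_oracle_n5(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        res = spearman(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_spearman_p(x, y))

    def test_zero_variance_na(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert res.statistic is None
        assert res.status == "zero variance"

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])

    def test_large_n_t_approximation_close_to_scipy(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = x + rng.normal(scale=0.8, size=40)
        res = spearman(x, y)
        ref = spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.05)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_hand_computed_two_groups(self):
        # ranks 1..6; R1 = 6, R2 = 15; H = 12/42 * (12 + 75) - 21 = 27/7
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(27 / 7)

    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)

    def test_all_values_tied_na(self):
        res = kruskal_wallis([[5, 5], [5, 5]])
        assert res.statistic is None
        assert res.status == "all values tied"

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    def test_matches_scipy_with_ties(self):
        from scipy.stats import kruskal

        rng = np.random.default_rng(11)
        groups = [rng.integers(0, 8, size=7).tolist() for _ in range(3)]
        res = kruskal_wallis(groups)
        ref = kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


# ---------------------------------------------------------------------------
# Version abundance and environmental correlation
# ---------------------------------------------------------------------------

class TestVersionAbundance:
    def test_diagnostic_sequences_unique_genes(self):
        refs = diagnostic_sequences({
            "A": {"x": "AAA", "shared": "CCC"},
            "B": {"y": "GGG", "shared": "CCC"},
        })
        assert refs == {"A": "AAA", "B": "GGG"}

    def test_fallback_to_full_island(self):
        refs = diagnostic_sequences({
            "A": {"shared": "CCC"},
            "B": {"shared": "CCC", "y": "GGG"},
        })
        assert refs["A"] == "CCC"  # no unique gene -> full island

    def test_single_version_sample_concentrates_mass(self, small_population,
                                                     small_reads):
        from fgislands.pipeline import find_annotated_islands

        pop = small_population
        version_genes = {}
        for sid in pop.genomes:
            for cls, s, e, gids, prods in find_annotated_islands(pop.features[sid]):
                version = next(i.version for i in pop.truth.islands
                               if i.strain_id == sid)
                seq = pop.genomes[sid].sequence
                version_genes[version] = {
                    f.product_label: seq[f.start:f.end]
                    for f in pop.features[sid]
                    if f.gene_id in set(gids)
                }
        refs = diagnostic_sequences(version_genes)
        vam = version_abundance(small_reads, refs, pop.truth.phosphate)
        # S1 (1 µM) is dominated by the version-A strain
        col = vam.abundance["S1"]
        assert col["A"] > 10 * max(col["E"], 1e-9)

    def test_relative_mode_columns_sum_to_one(self):
        ab = pd.DataFrame([[4.0, 0.0], [1.0, 0.0]], index=["A", "E"],
                          columns=["s1", "s2"])
        vam = VersionAbundanceMatrix(ab, pd.Series({"s1": 1.0, "s2": 0.1}))
        rel = vam.relative()
        assert rel["s1"].sum() == pytest.approx(1.0)
        assert rel["s2"].sum() == 0.0  # genome-free sample stays all-zero


class TestCorrelateVersions:
    def _matrix(self, values, phosphate):
        ab = pd.DataFrame(values, index=["A", "E"],
                          columns=list(phosphate))
        return VersionAbundanceMatrix(ab, pd.Series(phosphate))

    def test_sign_recovery(self):
        m = self._matrix(
            [[10.0, 5.0, 0.1], [0.1, 5.0, 10.0]],
            {"s1": 1.0, "s2": 0.05, "s3": 0.001},
        )
        table, kw = correlate_versions_with_environment(m)
        assert table.loc["A", "rho"] > 0
        assert table.loc["E", "rho"] < 0
        assert kw.statistic is not None

    def test_constant_phosphate_na(self):
        m = self._matrix(
            [[10.0, 5.0, 0.1], [0.1, 5.0, 10.0]],
            {"s1": 0.5, "s2": 0.5, "s3": 0.5},
        )
        table, _ = correlate_versions_with_environment(m)
        assert table["rho"].isna().all()

    def test_nothing_detected_raises(self):
        m = self._matrix(
            [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
            {"s1": 1.0, "s2": 0.1, "s3": 0.01},
        )
        with pytest.raises(ValueError, match="detected"):
            correlate_versions_with_environment(m)

    def test_version_in_single_sample_still_in_kruskal(self):
        m = self._matrix(
            [[10.0, 5.0, 1.0], [0.0, 0.0, 10.0]],
            {"s1": 1.0, "s2": 0.05, "s3": 0.001},
        )
        table, kw = correlate_versions_with_environment(m)
        assert kw.n > 0  # both versions contribute observations
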