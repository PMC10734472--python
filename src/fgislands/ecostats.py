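"""Nonparametric statistics tying island variants to the environment.

The Wilcoxon signed-rank test is exact for small n: the null distribution of
the rank sum over all 2^n sign assignments is computed in full (via a
convolution over the rank multiset, which enumerates the same distribution
without materialising every sign vector).  Spearman's rho uses exact
permutation enumeration for n <= 9.  Kruskal-Wallis applies the usual tie
correction with a chi-square reference.  All p-values are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata
from scipy.stats import t as t_dist

WILCOXON_EXACT_MAX_N = 25
SPEARMAN_EXACT_MAX_N = 9


@dataclass(frozen=True)
class StatResult:
    statistic: float | None
    p_value: float | None
    n: int
    method: str
    status: str = "ok"


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_distribution(double_ranks: Sequence[int]) -> np.ndarray:
    """Counts of W+ (on the doubled-rank scale) over all sign assignments."""
    total = sum(double_ranks)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return counts


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float] | None = None,
                         exact_max_n: int = WILCOXON_EXACT_MAX_N) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired values (or differences).

    Zero differences are dropped (Wilcoxon's original prescription); |d| is
    ranked with average ranks on ties; T = min(W+, W-).  For n <= 25 the
    two-sided p is exact over all 2^n sign assignments, otherwise a normal
    approximation with continuity and tie correction is used.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return StatResult(None, None, 0, "exact", status="all differences zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    t_stat = min(w_plus, w_minus)

    if n <= exact_max_n:
        double = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_distribution(double)
        total = counts.sum()  # 2^n
        double_t = int(round(2 * t_stat))
        p = 2.0 * counts[: double_t + 1].sum() / total
        return StatResult(t_stat, min(1.0, p), n, "exact")

    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (
        (tie_counts**3 - tie_counts).sum() / 48.0
    )
    z = (t_stat - mu + 0.5) / math.sqrt(var)
    p = 2.0 * norm.cdf(z)
    return StatResult(t_stat, min(1.0, p), n, "normal-approx")


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float((a * a).sum()) * float((b * b).sum()))
    return float((a * b).sum() / denom)


def spearman(x: Sequence[float], y: Sequence[float],
             exact_max_n: int = SPEARMAN_EXACT_MAX_N) -> StatResult:
    """Spearman rank correlation with a two-sided p-value.

    For n <= 9 the p-value is exact: the proportion of the n! rank
    permutations with |rho| at least as extreme as observed.  For larger n,
    the t-approximation with n - 2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult(None, None, n, "exact", status="zero variance")
    rx, ry = rankdata(x), rankdata(y)
    rho = _pearson(rx, ry)

    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = _pearson(rx, np.asarray(perm))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return StatResult(rho, count / total, n, "exact")

    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = 2.0 * t_dist.sf(abs(t), n - 2)
    return StatResult(rho, min(1.0, p), n, "t-approx")


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatResult:
    """Kruskal-Wallis H with tie correction; p from chi-square (k - 1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        raise ValueError("every group needs at least 1 observation")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = rankdata(pooled)
    h = 0.0
    offset = 0
    for s in sizes:
        r = ranks[offset:offset + s]
        h += r.sum() ** 2 / s
        offset += s
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    tie_counts = np.unique(pooled, return_counts=True)[1]
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction == 0:
        return StatResult(None, None, n, "chi2", status="all values tied")
    h /= correction
    p = float(chi2.sf(h, len(groups) - 1))
    return StatResult(h, p, n, "chi2")


# ---------------------------------------------------------------------------
# Version abundance and environmental correlation
# ---------------------------------------------------------------------------

@dataclass
class VersionAbundanceMatrix:
    """Versions x samples RPKG matrix with phosphate metadata attached."""

    abundance: pd.DataFrame
    phosphate: pd.Series

    def relative(self) -> pd.DataFrame:
        sums = self.abundance.sum(axis=0)
        return self.abundance.div(sums.where(sums > 0, np.nan), axis=1).fillna(0.0)


def diagnostic_sequences(
    version_gene_seqs: Mapping[str, Mapping[str, str]],
) -> dict[str, str]:
    """Concatenated version-diagnostic sequences.

    ``version_gene_seqs`` maps version -> {product_label: nucleotide seq}.
    A diagnostic gene belongs to exactly one version of the pool; versions
    without any diagnostic gene fall back to their full concatenated island
    sequence.
    """
    counts: dict[str, int] = {}
    for genes in version_gene_seqs.values():
        for product in genes:
            counts[product] = counts.get(product, 0) + 1
    refs: dict[str, str] = {}
    for version, genes in version_gene_seqs.items():
        diag = [seq for product, seq in genes.items() if counts[product] == 1]
        if diag:
            refs[version] = "".join(diag)
        else:
            refs[version] = "".join(genes.values())
        if not refs[version]:
            raise ValueError(f"version {version}: no diagnostic or fallback sequence")
    return refs


def version_abundance(
    reads_by_sample: Mapping[str, Sequence],
    version_refs: Mapping[str, str],
    phosphate: Mapping[str, float] | pd.Series,
    relative: bool = False,
) -> VersionAbundanceMatrix:
    """Recruit reads at the species tier against per-version reference
    sequences and tabulate RPKG per version and sample."""
    from .io_formats import SequenceRecord
    from .recruitment import GenomeIndex, compute_rpkg, filter_alignments, map_reads

    if not version_refs:
        raise ValueError("no version reference sequences")
    versions = sorted(version_refs)
    refs = {v: SequenceRecord(v, version_refs[v]) for v in versions}
    indexes = {v: GenomeIndex(refs[v]) for v in versions}
    samples = list(reads_by_sample)
    mat = pd.DataFrame(0.0, index=versions, columns=samples)
    for sample_id in samples:
        reads = list(reads_by_sample[sample_id])
        meta_size = sum(len(r.sequence) for r in reads)
        for v in versions:
            if meta_size == 0:
                continue
            hits = filter_alignments(
                map_reads(reads, refs[v], index=indexes[v]), "species"
            )
            mat.loc[v, sample_id] = compute_rpkg(
                len(hits), len(refs[v].sequence), meta_size
            )
    vam = VersionAbundanceMatrix(mat, pd.Series(dict(phosphate)))
    if relative:
        vam.abundance = vam.relative()
    return vam


def correlate_versions_with_environment(matrix: VersionAbundanceMatrix
                                        ) -> tuple[pd.DataFrame, StatResult]:
    """Per-version Spearman correlation with phosphate plus a Kruskal-Wallis
    test of phosphate across the sample sets where each version is detected."""
    ab = matrix.abundance
    phosphate = matrix.phosphate.reindex(ab.columns)
    if phosphate.isna().any():
        raise ValueError("phosphate value missing for some samples")
    if len(ab.columns) < 3:
        raise ValueError("need phosphate values for at least 3 samples")
    if not (ab.to_numpy() > 0).any():
        raise ValueError("no version detected in any sample")

    rows = []
    groups = []
    group_labels = []
    for version in ab.index:
        values = ab.loc[version]
        detected = values[values > 0]
        rho = p = None
        status = "ok"
        if np.ptp(phosphate.to_numpy()) == 0 or np.ptp(values.to_numpy()) == 0:
            status = "zero variance"
        elif len(values) >= 3:
            res = spearman(values.to_numpy(), phosphate.to_numpy())
            rho, p, status = res.statistic, res.p_value, res.status
        rows.append(
            {"version": version, "rho": rho, "p_value": p,
             "n_samples_detected": len(detected), "status": status}
        )
        if len(detected) >= 1:
            groups.append(phosphate.loc[detected.index].to_numpy())
            group_labels.append(version)
    table = pd.DataFrame(rows).set_index("version")
    if len(groups) >= 2:
        kw = kruskal_wallis(groups)
    else:
        kw = StatResult(None, None, 0, "chi2", status="fewer than 2 detected versions")
    return table, kw
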