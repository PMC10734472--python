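import numpy as np
import pytest

from fgislands.io_formats import GeneFeature, SequenceRecord
from fgislands.island_scan import IslandCall
from fgislands.island_typing import (
    assign_version,
    carrier_prevalence,
    cluster_marker_sequences,
    compute_aai,
    extract_island_genes,
    global_identity,
    island_vs_genome_aai,
)
from fgislands.signatures import (
    FGIP_SIGNATURES,
    FGIPHN_SIGNATURES,
    PST_CORE,
    VersionSignature,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


class TestSignatures:
    def test_every_fgip_version_contains_pst_core(self):
        for sig in FGIP_SIGNATURES.values():
            assert set(PST_CORE) <= sig.required_set

    def test_fgip_c_has_19_genes(self):
        assert len(FGIP_SIGNATURES["C"].required_set) == 19

    def test_required_forbidden_disjoint_enforced(self):
        with pytest.raises(ValueError, match="overlap"):
            VersionSignature("fGIp", "X", ("pstS",), ("pstS",))


class TestAssignVersion:
    def test_pst_core_plus_methyltransferase_is_A(self):
        genes = set(PST_CORE) | {"set_mtase"}
        assert assign_version(genes, "fGIp").label == "A"

    def test_full_19_gene_inventory_is_C(self):
        assert assign_version(FGIP_SIGNATURES["C"].required_set, "fGIp").label == "C"

    def test_phn_without_phnG_is_B(self):
        genes = {"phnC", "phnD", "phnE", "phnH", "phnI", "phnJ", "phnK",
                 "phnL", "phnM"}
        assert assign_version(genes, "fGIphn").label == "B"

    @pytest.mark.parametrize("label", list(FGIP_SIGNATURES))
    def test_fgip_inventories_round_trip(self, label):
        got = assign_version(FGIP_SIGNATURES[label].required_set, "fGIp")
        assert got.label == label
        assert got.score == 1.0

    @pytest.mark.parametrize("label", list(FGIPHN_SIGNATURES))
    def test_fgiphn_inventories_round_trip(self, label):
        got = assign_version(FGIPHN_SIGNATURES[label].required_set, "fGIphn")
        assert got.label == label

    def test_incomplete_core_unassigned(self):
        genes = {"pstS", "pstC", "set_mtase"}  # missing pstA/pstB/phoU
        assert assign_version(genes, "fGIp").label == "unassigned"

    def test_unknown_class_raises(self):
        with pytest.raises(ValueError, match="island class"):
            assign_version({"pstS"}, "fGIx")


class TestExtractIslandGenes:
    ISLAND = IslandCall("g1", 1000, 3000, "x")

    def test_gene_fully_inside_included(self):
        f = GeneFeature("g1", "a", 1200, 1800)
        assert extract_island_genes(self.ISLAND, [f]) == [f]

    def test_gene_40_percent_inside_excluded(self):
        f = GeneFeature("g1", "a", 2600, 3600)  # 400 of 1000 inside
        assert extract_island_genes(self.ISLAND, [f]) == []

    def test_gene_exactly_half_inside_included(self):
        f = GeneFeature("g1", "a", 2500, 3500)
        assert extract_island_genes(self.ISLAND, [f]) == [f]

    def test_empty_island_empty_set(self):
        island = IslandCall("g1", 10, 20, "x")
        assert extract_island_genes(island, []) == []


class TestCarrierPrevalence:
    def test_24_of_150_is_16_percent(self):
        flags = [True] * 24 + [False] * 126
        assert carrier_prevalence(flags) == 16.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            carrier_prevalence([])


class TestMarkerClustering:
    def _markers(self, seqs):
        return {
            gid: {"pstS": s[0], "pstC": s[1], "pstA": s[2]}
            for gid, s in seqs.items()
        }

    def test_identical_sequences_one_cluster(self):
        m = self._markers({
            "g1": ("MKL" * 30, "AVL" * 30, "TRE" * 30),
            "g2": ("MKL" * 30, "AVL" * 30, "TRE" * 30),
        })
        out = cluster_marker_sequences(m)
        assert out.dedup == {"g1": ["g1", "g2"]}
        assert out.newick.endswith(";")

    def test_single_sequence_trivial_output(self):
        m = self._markers({"g1": ("MKL" * 30, "AVL" * 30, "TRE" * 30)})
        out = cluster_marker_sequences(m)
        assert out.clusters == {"g1": 1}
        assert out.newick == "g1;"

    def test_p_distance_matches_substitution_count(self, rng):
        s = "".join(rng.choice(AA, size=300))
        arr = np.array(list(s))
        pos = rng.choice(300, size=30, replace=False)  # 10% of sites
        for p in pos:
            arr[p] = AA[(AA.index(arr[p]) + 1) % 20]
        m = self._markers({
            "g1": (s[:100], s[100:200], s[200:]),
            "g2": ("".join(arr[:100]), "".join(arr[100:200]), "".join(arr[200:])),
        })
        out = cluster_marker_sequences(m)
        assert out.distances.loc["g1", "g2"] == pytest.approx(0.10, abs=0.01)

    def test_missing_subunit_skipped_with_warning(self, caplog):
        m = {
            "g1": {"pstS": "MKL" * 30, "pstC": "AVL" * 30, "pstA": "TRE" * 30},
            "g2": {"pstS": "MKL" * 30, "pstC": "", "pstA": "TRE" * 30},
        }
        with caplog.at_level("WARNING"):
            out = cluster_marker_sequences(m)
        assert "g2" in caplog.text
        assert list(out.dedup) == ["g1"]

    def test_dedup_never_merges_different_sequences(self, rng):
        s1 = "".join(rng.choice(AA, size=90))
        s2 = s1[:-1] + ("A" if s1[-1] != "A" else "C")  # one site apart
        m = self._markers({"g1": (s1, s1, s1), "g2": (s2, s1, s1)})
        out = cluster_marker_sequences(m)
        assert len(out.dedup) == 2


class TestAai:
    def _protein_set(self, rng, n=5, length=120, prefix="p"):
        return [
            SequenceRecord(f"{prefix}{i}", "".join(rng.choice(AA, size=length)))
            for i in range(n)
        ]

    def test_identical_sets_aai_100(self, rng):
        a = self._protein_set(rng)
        r = compute_aai(a, a)
        assert r.aai == pytest.approx(100.0)
        assert r.n_bbh == len(a)

    def test_no_qualifying_pairs_na(self, rng):
        a = self._protein_set(rng, n=3, prefix="a")
        b = self._protein_set(rng, n=3, prefix="b")
        r = compute_aai(a, b)
        assert r.aai is None

    def test_known_20_percent_substitutions(self, rng):
        a = self._protein_set(rng, n=4, length=200)
        b = []
        for rec in a:
            arr = np.array(list(rec.sequence))
            pos = rng.choice(len(arr), size=40, replace=False)  # 20%
            for p in pos:
                arr[p] = AA[(AA.index(arr[p]) + 1) % 20]
            b.append(SequenceRecord(rec.id + "_mut", "".join(arr)))
        r = compute_aai(a, b)
        assert r.aai == pytest.approx(80.0, abs=1.0)
        assert r.n_bbh == 4

    def test_symmetry(self, rng):
        a = self._protein_set(rng, n=3, prefix="a")
        b = [SequenceRecord(r.id + "m", r.sequence[:100] + "W" * 20) for r in a]
        fwd = compute_aai(a, b)
        rev = compute_aai(b, a)
        assert fwd.aai == pytest.approx(rev.aai)
        assert fwd.n_bbh == rev.n_bbh

    def test_empty_set_raises(self, rng):
        with pytest.raises(ValueError):
            compute_aai([], self._protein_set(rng))


class TestIslandVsGenomeAai:
    def test_paired_table_shape(self):
        pairs = {v: (99.0, 92.0) for v in "ABCDEFGH"}
        table = island_vs_genome_aai(pairs)
        assert len(table) == 8
        assert list(table.columns) == ["island_aai", "genome_aai"]

    def test_fewer_than_two_pairs_raises(self):
        with pytest.raises(ValueError):
            island_vs_genome_aai({"A": (99.0, 92.0)})

    def test_simulated_island_exchange_island_aai_exceeds_genome_aai(self):
        # strains of different species share identical island cassettes
        from fgislands.synthetic_community import (
            IslandLocus, SimulationConfig, build_population,
        )

        cfg = SimulationConfig(
            seed=31, core_length=20_000, n_species=2, strains_per_species=1,
            strain_versions=[{"fGIp": "A"}, {"fGIp": "A"}],
            island_loci=[IslandLocus("fGIp", 9_000, ("A",))],
        )
        pop = build_population(cfg)
        ids = sorted(pop.genomes)
        island_prots, genome_prots = {}, {}
        for sid in ids:
            isl = next(i for i in pop.truth.islands if i.strain_id == sid)
            feats = pop.features[sid]
            in_island = {
                f"{sid}|{f.gene_id}"
                for f in feats if isl.start <= f.start and f.end <= isl.end
            }
            island_prots[sid] = [p for p in pop.proteins[sid] if p.id in in_island]
            genome_prots[sid] = [p for p in pop.proteins[sid]
                                 if p.id not in in_island][:15]
        aai_island = compute_aai(island_prots[ids[0]], island_prots[ids[1]])
        aai_genome = compute_aai(genome_prots[ids[0]], genome_prots[ids[1]])
        assert aai_island.aai == pytest.approx(100.0)
        assert aai_genome.aai < aai_island.aai


class TestGlobalIdentity:
    def test_identical(self):
        assert global_identity("MKLV" * 20, "MKLV" * 20)[0] == pytest.approx(100.0)

    def test_zero_length_raises(self):
        with pytest.raises(ValueError):
            global_identity("", "MKL")
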