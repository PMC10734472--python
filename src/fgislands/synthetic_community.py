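"""Synthetic clonal populations and metagenomes with full ground truth.

The simulator builds one or more bacterial "species", each a randomly drawn
core genome, and derives strains from each species by applying substitution
mutations (no indels, so island loci stay positionally equivalent across
strains).  Flexible islands are inserted at fixed loci between conserved
border genes; the gene content of each island version follows the built-in
signature tables.  Shotgun reads are then drawn along a configurable
phosphate gradient: gene-poor island versions are weighted up at high
phosphate and gene-rich versions at low phosphate, so the downstream
environment-correlation statistics have a known sign to recover.

All randomness flows from a single generator seeded from the config; draws
happen in a fixed documented order (species cores, strain mutations, island
cassettes, then reads sample by sample), so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import (
    GeneFeature,
    SequenceRecord,
    write_fasta,
    write_fastq,
    write_gff3,
)
from .signatures import signatures_for, version_rank

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IslandLocus:
    """A fixed genomic locus at which island versions are inserted."""

    locus_name: str
    insertion_position: int
    version_pool: tuple[str, ...]

    @property
    def island_class(self) -> str:
        if self.locus_name.startswith("fGIphn"):
            return "fGIphn"
        if self.locus_name.startswith("fGIp"):
            return "fGIp"
        return "custom"


@dataclass
class SimulationConfig:
    seed: int = 0
    core_length: int = 100_000
    gene_length: int = 900
    intergenic: int = 3
    n_species: int = 1
    strains_per_species: int = 2
    within_species_divergence: float = 0.005
    between_species_divergence: float = 0.08
    #: nucleotide divergence between versions of the same locus gene family
    version_divergence: float = 0.2
    island_loci: list[IslandLocus] = field(default_factory=list)
    #: genes in a per-strain private cassette at "custom" loci
    unique_cassette_genes: int = 8
    read_length: int = 150
    per_base_error: float = 0.005
    depth_per_strain: float = 10.0
    #: steepness and midpoint (µM) of the logistic abundance model
    abundance_gain: float = 6.0
    abundance_midpoint: float = 0.05
    samples: list[tuple[str, float]] = field(default_factory=list)
    #: optional explicit per-strain version assignment, one dict per strain
    #: (ordered sp1 strains, then sp2, ...); default is round-robin per pool
    strain_versions: list[dict[str, str]] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.within_species_divergence < self.between_species_divergence):
            raise ValueError("require 0 < within < between species divergence")
        for locus in self.island_loci:
            if not (0 < locus.insertion_position < self.core_length):
                raise ValueError(
                    f"insertion position {locus.insertion_position} of "
                    f"{locus.locus_name} not strictly inside the core"
                )
            if locus.island_class != "custom":
                table = signatures_for(locus.island_class)
                for v in locus.version_pool:
                    if v != "unique" and v not in table:
                        raise ValueError(
                            f"{locus.locus_name}: unknown version signature {v!r}"
                        )
        for sample_id, phosphate in self.samples:
            if phosphate <= 0:
                raise ValueError(f"sample {sample_id}: phosphate must be > 0")


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class IslandTruth:
    strain_id: str
    locus_name: str
    start: int
    end: int
    version: str


@dataclass
class SyntheticTruth:
    #: strain_id -> (species_id, {locus: version})
    strains: pd.DataFrame
    islands: list[IslandTruth]
    #: strains x samples, columns sum to 1
    abundances: pd.DataFrame
    #: phosphate (µM) per sample
    phosphate: pd.Series
    #: filled by simulate_reads: read_id, sample_id, strain_id, pos, strand, n_errors
    provenance: pd.DataFrame | None = None


@dataclass
class Population:
    genomes: dict[str, SequenceRecord]
    features: dict[str, list[GeneFeature]]
    proteins: dict[str, list[SequenceRecord]]
    truth: SyntheticTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Mutation primitives
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, alphabet: np.ndarray) -> np.ndarray:
    return alphabet[rng.integers(0, len(alphabet), length)]

def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float,
            alphabet: np.ndarray) -> np.ndarray:
    """Substitute a Binomial(L, rate) number of sites to a different letter."""
    out = seq.copy()
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return out
    pos = rng.choice(len(seq), size=n, replace=False)
    # shift within the alphabet guarantees the new letter differs
    idx = np.searchsorted(alphabet, out[pos])
    shift = rng.integers(1, len(alphabet), size=n)
    out[pos] = alphabet[(idx + shift) % len(alphabet)]
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Abundance model
# ---------------------------------------------------------------------------

def abundance_model(phosphate_um: float, rank: float, gain: float = 6.0,
                    midpoint_um: float = 0.05) -> float:
    """Logistic weight of an island version along the phosphate gradient.

    ``rank`` in [0, 1] orders versions by gene richness; gene-poor versions
    (rank < 0.5) increase with phosphate, gene-rich versions decrease, and
    versions of equal rank get equal weights.  The paper observes only the
    monotone association, so gain and midpoint are configuration, not fixed
    constants.
    """
    if phosphate_um <= 0:
        raise ValueError("phosphate concentration must be > 0")
    slope = (0.5 - rank) * 2.0
    x = np.log10(phosphate_um) - np.log10(midpoint_um)
    return float(expit(gain * slope * x))


# ---------------------------------------------------------------------------
# Population construction
# ---------------------------------------------------------------------------

def _cassette_layout(genes: Sequence[str], gene_length: int, intergenic: int
                     ) -> tuple[int, list[tuple[str, int, int]]]:
    """Offsets of cassette genes within an island; returns (total_len, layout)."""
    layout = []
    pos = 0
    for i, product in enumerate(genes):
        layout.append((product, pos, pos + gene_length))
        pos += gene_length
        if i != len(genes) - 1:
            pos += intergenic
    return pos, layout


def build_population(config: SimulationConfig) -> Population:
    """Build strain genomes, annotations, proteins and ground truth."""
    rng = np.random.default_rng(config.seed)
    gl, ig = config.gene_length, config.intergenic
    period = gl + ig

    # -- ancestral core and per-core-gene ancestral proteins
    root_nt = _random_seq(rng, config.core_length, _NT)
    n_core_genes = 0
    core_gene_spans: list[tuple[int, int]] = []
    pos = 0
    while pos + gl <= config.core_length:
        core_gene_spans.append((pos, pos + gl))
        pos += period
        n_core_genes += 1
    root_aa = [_random_seq(rng, gl // 3, _AA) for _ in range(n_core_genes)]

    # -- species cores
    half_between = config.between_species_divergence / 2.0
    half_within = config.within_species_divergence / 2.0
    species_nt, species_aa = [], []
    for _ in range(config.n_species):
        species_nt.append(_mutate(rng, root_nt, half_between, _NT))
        species_aa.append([_mutate(rng, a, half_between, _AA) for a in root_aa])

    # -- island cassettes: one base gene family per (locus, product), one
    #    concrete sequence per (locus, version)
    loci = sorted(config.island_loci, key=lambda l: l.insertion_position)
    # snap each insertion point to the end of the nearest core gene so the
    # upstream gene is a clean conserved border
    snapped: list[tuple[IslandLocus, int, int]] = []  # (locus, border_idx, pos)
    for locus in loci:
        idx = min(
            range(n_core_genes),
            key=lambda i: abs(core_gene_spans[i][1] - locus.insertion_position),
        )
        snapped.append((locus, idx, core_gene_spans[idx][1]))

    cassette_seqs: dict[tuple[str, str], np.ndarray] = {}
    cassette_layouts: dict[tuple[str, str], list[tuple[str, int, int]]] = {}
    base_gene: dict[tuple[str, str], np.ndarray] = {}
    base_prot: dict[tuple[str, str], np.ndarray] = {}

    def _family(locus_name: str, product: str) -> tuple[np.ndarray, np.ndarray]:
        key = (locus_name, product)
        if key not in base_gene:
            base_gene[key] = _random_seq(rng, gl, _NT)
            base_prot[key] = _random_seq(rng, gl // 3, _AA)
        return base_gene[key], base_prot[key]

    cassette_prots: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for locus, _idx, _pos in snapped:
        if locus.island_class == "custom":
            continue
        table = signatures_for(locus.island_class)
        for version in locus.version_pool:
            if version == "unique":
                continue
            genes = table[version].required
            total, layout = _cassette_layout(genes, gl, ig)
            seq = np.zeros(total, dtype=np.uint8)
            prots: dict[str, np.ndarray] = {}
            for product, s, e in layout:
                fam_nt, fam_aa = _family(locus.locus_name, product)
                seq[s:e] = _mutate(rng, fam_nt, config.version_divergence, _NT)
                prots[product] = _mutate(rng, fam_aa, config.version_divergence, _AA)
            # fill intergenic gaps with random bases
            gaps = seq == 0
            seq[gaps] = _random_seq(rng, int(gaps.sum()), _NT)
            cassette_seqs[(locus.locus_name, version)] = seq
            cassette_layouts[(locus.locus_name, version)] = layout
            cassette_prots[(locus.locus_name, version)] = prots

    # -- strain roster and version assignment
    strain_rows = []
    all_strains: list[tuple[str, int]] = []
    for sp in range(config.n_species):
        for st in range(config.strains_per_species):
            strain_id = f"sp{sp + 1}_st{st + 1}"
            all_strains.append((strain_id, sp))

    assignments: list[dict[str, str]] = []
    for k, (strain_id, sp) in enumerate(all_strains):
        if config.strain_versions is not None:
            versions = dict(config.strain_versions[k])
        else:
            st = k - sp * config.strains_per_species
            versions = {
                locus.locus_name: locus.version_pool[st % len(locus.version_pool)]
                for locus in loci
            }
        assignments.append(versions)
        strain_rows.append(
            {"strain_id": strain_id, "species_id": f"sp{sp + 1}", **versions}
        )

    # -- assemble each strain genome
    genomes: dict[str, SequenceRecord] = {}
    features: dict[str, list[GeneFeature]] = {}
    proteins: dict[str, list[SequenceRecord]] = {}
    island_truth: list[IslandTruth] = []

    for k, (strain_id, sp) in enumerate(all_strains):
        core = _mutate(rng, species_nt[sp], half_within, _NT)
        aa = [_mutate(rng, a, half_within, _AA) for a in species_aa[sp]]
        versions = assignments[k]

        segments: list[np.ndarray] = []
        feats: list[GeneFeature] = []
        prots: list[SequenceRecord] = []
        cursor = 0  # position in core coords
        offset = 0  # accumulated inserted length
        gene_no = 0

        def _emit_core_genes(limit_idx: int) -> None:
            nonlocal gene_no
            while gene_no < limit_idx:
                s, e = core_gene_spans[gene_no]
                feats.append(
                    GeneFeature(strain_id, f"{strain_id}_g{gene_no + 1:04d}",
                                s + offset, e + offset, "+", "hp")
                )
                prots.append(
                    SequenceRecord(f"{strain_id}|{strain_id}_g{gene_no + 1:04d}",
                                   _to_str(aa[gene_no]))
                )
                gene_no += 1

        for locus, border_idx, ins_pos in snapped:
            version = versions.get(locus.locus_name)
            if version is None:
                continue
            _emit_core_genes(border_idx + 1)
            segments.append(core[cursor:ins_pos])
            cursor = ins_pos
            island_start = ins_pos + offset

            if version == "unique" or locus.island_class == "custom":
                genes = tuple(["hp"] * config.unique_cassette_genes)
                total, layout = _cassette_layout(genes, gl, ig)
                seq = _random_seq(rng, total, _NT)
                prot_map = {
                    f"{p}#{i}": _random_seq(rng, gl // 3, _AA)
                    for i, (p, _s, _e) in enumerate(layout)
                }
            else:
                seq = cassette_seqs[(locus.locus_name, version)]
                layout = cassette_layouts[(locus.locus_name, version)]
                prot_map = {
                    f"{p}#{i}": cassette_prots[(locus.locus_name, version)][p]
                    for i, (p, _s, _e) in enumerate(layout)
                }
            segments.append(seq)
            for i, (product, s, e) in enumerate(layout):
                gid = f"{strain_id}_{locus.locus_name}_{i + 1:02d}_{product}"
                feats.append(
                    GeneFeature(strain_id, gid, island_start + s, island_start + e,
                                "+", product)
                )
                prots.append(
                    SequenceRecord(f"{strain_id}|{gid}", _to_str(prot_map[f"{product}#{i}"]))
                )
            offset += len(seq)
            island_truth.append(
                IslandTruth(strain_id, locus.locus_name, island_start,
                            island_start + len(seq), version)
            )

        _emit_core_genes(n_core_genes)
        segments.append(core[cursor:])
        genome = np.concatenate(segments) if segments else core
        genomes[strain_id] = SequenceRecord(strain_id, _to_str(genome))
        feats.sort(key=lambda f: f.start)
        features[strain_id] = feats
        proteins[strain_id] = prots

    # -- per-sample strain abundances along the phosphate gradient
    strains_df = pd.DataFrame(strain_rows).set_index("strain_id")
    sample_ids = [s for s, _ in config.samples]
    phosphate = pd.Series({s: p for s, p in config.samples}, name="phosphate_uM")
    weights = np.ones((len(all_strains), len(sample_ids)))
    for i, (strain_id, sp) in enumerate(all_strains):
        for j, (sample_id, p_um) in enumerate(config.samples):
            w = 1.0
            for locus in loci:
                version = assignments[i].get(locus.locus_name)
                if version is None or version == "unique" or locus.island_class == "custom":
                    continue
                rank = version_rank(locus.island_class, version)
                w *= abundance_model(
                    p_um, rank, config.abundance_gain, config.abundance_midpoint
                )
            weights[i, j] = w
    if sample_ids:
        weights = weights / weights.sum(axis=0, keepdims=True)
    abundances = pd.DataFrame(
        weights, index=[s for s, _ in all_strains], columns=sample_ids
    )

    truth = SyntheticTruth(
        strains=strains_df, islands=island_truth, abundances=abundances,
        phosphate=phosphate,
    )
    return Population(genomes, features, proteins, truth, config)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_reads(population: Population, config: SimulationConfig | None = None
                   ) -> dict[str, list[SequenceRecord]]:
    """Draw shotgun reads per sample; read counts are computed, not sampled.

    Each strain contributes round(abundance x depth x genome_length /
    read_length) reads, drawn uniformly along the genome with i.i.d.
    substitution errors.  Read ids encode provenance, which is also recorded
    in the truth table.
    """
    config = config or population.config
    rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length
    truth = population.truth

    reads_by_sample: dict[str, list[SequenceRecord]] = {}
    prov_rows = []
    for sample_id in truth.abundances.columns:
        reads: list[SequenceRecord] = []
        for strain_id in truth.abundances.index:
            genome = population.genomes[strain_id].sequence
            if rl > len(genome):
                raise ValueError(
                    f"read length {rl} exceeds genome length of {strain_id}"
                )
            ab = float(truth.abundances.loc[strain_id, sample_id])
            n_reads = int(round(ab * config.depth_per_strain * len(genome) / rl))
            if n_reads == 0:
                continue
            garr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
            starts = rng.integers(0, len(genome) - rl + 1, size=n_reads)
            strands = rng.random(n_reads) < 0.5
            n_errors = rng.binomial(rl, config.per_base_error, size=n_reads)
            for i in range(n_reads):
                frag = garr[starts[i]:starts[i] + rl].copy()
                if n_errors[i]:
                    epos = rng.choice(rl, size=n_errors[i], replace=False)
                    idx = np.searchsorted(_NT, frag[epos])
                    shift = rng.integers(1, 4, size=n_errors[i])
                    frag[epos] = _NT[(idx + shift) % 4]
                seq = _to_str(frag)
                strand = "-" if strands[i] else "+"
                if strand == "-":
                    seq = reverse_complement(seq)
                rid = f"{sample_id}|{strain_id}|{i}|{starts[i]}|{strand}|{n_errors[i]}"
                reads.append(SequenceRecord(rid, seq))
                prov_rows.append(
                    (rid, sample_id, strain_id, int(starts[i]), strand, int(n_errors[i]))
                )
        reads_by_sample[sample_id] = reads
    truth.provenance = pd.DataFrame(
        prov_rows,
        columns=["read_id", "sample_id", "strain_id", "pos", "strand", "n_errors"],
    )
    return reads_by_sample


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_population(population: Population, outdir: str | Path) -> None:
    """Write genomes, proteins, annotations, metadata and truth tables."""
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "proteins").mkdir(exist_ok=True)
    (outdir / "annotations").mkdir(exist_ok=True)
    for strain_id, genome in population.genomes.items():
        write_fasta([genome], outdir / "genomes" / f"{strain_id}.fasta")
        write_fasta(population.proteins[strain_id],
                    outdir / "proteins" / f"{strain_id}.faa")
        write_gff3(population.features[strain_id],
                   outdir / "annotations" / f"{strain_id}.gff3")
    truth = population.truth
    truth.strains.to_csv(outdir / "truth_strains.tsv", sep="\t")
    pd.DataFrame(
        [(i.strain_id, i.locus_name, i.start, i.end, i.version)
         for i in truth.islands],
        columns=["strain_id", "locus_name", "start", "end", "version"],
    ).to_csv(outdir / "truth_islands.tsv", sep="\t", index=False)
    truth.abundances.to_csv(outdir / "truth_abundances.tsv", sep="\t")
    meta = pd.DataFrame({
        "sample_id": truth.phosphate.index,
        "phosphate_uM": truth.phosphate.values,
    })
    meta.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    if truth.provenance is not None:
        truth.provenance.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)


def write_reads(reads_by_sample: dict[str, list[SequenceRecord]],
                outdir: str | Path) -> None:
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    for sample_id, reads in reads_by_sample.items():
        write_fastq(reads, outdir / "reads" / f"{sample_id}.fastq")
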