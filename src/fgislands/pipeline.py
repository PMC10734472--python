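"""End-to-end orchestration: simulate -> recruit -> islands -> genomospecies
-> type islands -> environment statistics, with a manifest for provenance.

Every stage communicates through plain files (FASTA/FASTQ/GFF3/BED/TSV), so
any stage can be re-run or replaced independently — e.g. real-data users can
substitute BLAST tabular alignments for the internal mapper's output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecostats, genomospecies, island_scan, island_typing, recruitment
from .io_formats import GeneFeature, SequenceRecord, write_bed, write_tsv
from .island_scan import ScanParams
from .synthetic_community import (
    IslandLocus,
    Population,
    SimulationConfig,
    build_population,
    simulate_reads,
    write_population,
    write_reads,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "fgi_run"
    seed: int = 42
    reference: str | None = None  # default: first strain
    log_level: str = "INFO"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scan: ScanParams = field(default_factory=ScanParams)


def demo_config(outdir: str = "fgi_run", seed: int = 42) -> PipelineConfig:
    """Bundled desk-scale demo: one species, four strains, two island loci,
    three samples along a phosphate gradient."""
    sim = SimulationConfig(
        seed=seed,
        core_length=100_000,
        n_species=1,
        strains_per_species=4,
        island_loci=[
            IslandLocus("fGIp", 40_000, ("A", "E")),
            IslandLocus("lps", 70_000, ("unique", "unique", "unique", "unique")),
        ],
        depth_per_strain=40.0,
        samples=[("S_highP", 1.0), ("S_midP", 0.05), ("S_lowP", 0.002)],
    )
    return PipelineConfig(outdir=outdir, seed=seed, simulation=sim)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("simulation", {})
    loci = [
        IslandLocus(l["locus_name"], int(l["insertion_position"]),
                    tuple(l["version_pool"]))
        for l in sim_raw.pop("island_loci", [])
    ]
    samples = [tuple(s) for s in sim_raw.pop("samples", [])]
    sim = SimulationConfig(island_loci=loci, samples=samples, **sim_raw)
    scan = ScanParams(**raw.pop("scan", {}))
    return PipelineConfig(simulation=sim, scan=scan, **raw)


# ---------------------------------------------------------------------------
# Annotation-based island discovery (gene-signature matching)
# ---------------------------------------------------------------------------

def find_annotated_islands(features, island_class: str | None = None):
    """Locate islands on a genome from its gene annotations.

    Maximal runs of non-"hp" vocabulary genes (with interior "hp" genes
    absorbed) are island cassettes; a run is classed "fGIphn" when it
    contains phn genes, "fGIp" when it contains the pst operon.  This
    replaces profile-HMM gene recovery on the exactly annotated synthetic
    path.
    """
    runs: list[list[GeneFeature]] = []
    current: list[GeneFeature] = []
    pending_hp: list[GeneFeature] = []
    for f in sorted(features, key=lambda f: f.start):
        if f.product_label == "hp":
            if current:
                pending_hp.append(f)
            continue
        if current and pending_hp and len(pending_hp) <= 1:
            current.extend(pending_hp)
        elif current and pending_hp:
            runs.append(current)
            current = []
        pending_hp = []
        current.append(f)
    if current:
        runs.append(current)

    out = []
    for run in runs:
        products = {f.product_label for f in run}
        if products & {"phnH", "phnI", "phnJ"}:
            cls = "fGIphn"
        elif products & {"pstS", "pstC", "pstA"}:
            cls = "fGIp"
        else:
            cls = "custom"
        if island_class is not None and cls != island_class:
            continue
        out.append((cls, run[0].start, run[-1].end, sorted(f.gene_id for f in run),
                    sorted(products)))
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory containing stage outputs
    and a manifest with parameters, seeds and output checksums."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- stage 1: simulate
    logger.info("stage simulate")
    population = build_population(config.simulation)
    reads = simulate_reads(population)
    write_population(population, outdir)
    write_reads(reads, outdir)
    truth = population.truth
    samples = list(truth.abundances.columns)

    # -- stage 2: recruit reference genome(s)
    logger.info("stage recruit")
    ref_id = config.reference or sorted(population.genomes)[0]
    reference = population.genomes[ref_id]
    profiles: dict[str, recruitment.RecruitmentProfile] = {}
    presence: dict[str, recruitment.PresenceCall] = {}
    index = recruitment.GenomeIndex(reference)
    for sample_id in samples:
        prof = recruitment.recruit(reads[sample_id], reference, sample_id,
                                   index=index)
        profiles[sample_id] = prof
        presence[sample_id] = recruitment.call_presence(prof)
    pres_df = pd.DataFrame(
        [
            {"sample_id": s, "genome_id": ref_id, "rpkg": p.rpkg,
             "breadth98": p.breadth98, "present": p.present}
            for s, p in presence.items()
        ]
    ).set_index("sample_id")
    write_tsv(pres_df, outdir / "presence.tsv")

    # -- stage 3: island scan on the reference
    logger.info("stage islands")
    calls = island_scan.scan_genome(
        profiles, presence, population.features[ref_id], config.scan
    )
    write_bed(calls, outdir / "islands.bed")
    flag_df = pd.DataFrame(
        [
            {"locus_label": c.locus_label, "start": c.start, "end": c.end,
             "category": c.category, **c.per_sample_flag}
            for c in calls
        ]
    )
    if not flag_df.empty:
        flag_df = flag_df.set_index("locus_label")
    write_tsv(flag_df, outdir / "islands.tsv")

    # -- stage 4: ANI, dereplication, genomospecies
    logger.info("stage genomospecies")
    genome_list = [population.genomes[g] for g in sorted(population.genomes)]
    ani = genomospecies.ani_matrix(genome_list)
    write_tsv(ani, outdir / "ani.tsv")
    reps, membership = genomospecies.dereplicate(genome_list, ani=ani)
    rpkg_rows = {}
    for g in reps:
        gindex = recruitment.GenomeIndex(g) if g.id != ref_id else index
        row = {}
        for sample_id in samples:
            prof = recruitment.recruit(reads[sample_id], g, sample_id, index=gindex)
            row[sample_id] = prof.rpkg
        rpkg_rows[g.id] = row
    rpkg = pd.DataFrame(rpkg_rows).T.reindex(columns=samples)
    write_tsv(rpkg, outdir / "rpkg.tsv")
    assignments = genomospecies.assign_genomospecies(
        [g.id for g in reps], ani, rpkg,
        presence=rpkg >= recruitment.PRESENCE_MIN_RPKG,
    )
    gs_df = pd.DataFrame([asdict(a) for a in assignments]).set_index("genome_id")
    write_tsv(gs_df, outdir / "genomospecies.tsv")

    # -- stage 5: type islands across all strains
    logger.info("stage type-islands")
    typing_rows = []
    version_islands: dict[str, dict[str, dict[str, str]]] = {}  # class -> version -> genes
    for strain_id in sorted(population.genomes):
        feats = population.features[strain_id]
        genome_seq = population.genomes[strain_id].sequence
        for cls, start, end, gene_ids, products in find_annotated_islands(feats):
            if cls == "custom":
                continue
            assignment = island_typing.assign_version(products, cls)
            typing_rows.append(
                {"genome_id": strain_id, "island_class": cls, "start": start,
                 "end": end, "version": assignment.label,
                 "score": assignment.score}
            )
            if assignment.label != "unassigned":
                store = version_islands.setdefault(cls, {})
                if assignment.label not in store:
                    gene_seqs = {
                        f.product_label: genome_seq[f.start:f.end]
                        for f in feats
                        if f.gene_id in set(gene_ids)
                    }
                    store[assignment.label] = gene_seqs
    typing_df = pd.DataFrame(typing_rows)
    write_tsv(typing_df, outdir / "island_versions.tsv")

    # -- stage 6: version abundance and environment statistics
    logger.info("stage stats")
    stats_outputs = {}
    for cls, versions in version_islands.items():
        refs = ecostats.diagnostic_sequences(versions)
        vam = ecostats.version_abundance(reads, refs, truth.phosphate)
        write_tsv(vam.abundance, outdir / f"abundance_{cls}.tsv")
        table, kw = ecostats.correlate_versions_with_environment(vam)
        summary = table.copy()
        summary.loc["__kruskal_wallis__"] = {
            "rho": kw.statistic, "p_value": kw.p_value,
            "n_samples_detected": kw.n, "status": kw.status,
        }
        write_tsv(summary, outdir / f"stats_{cls}.tsv")
        stats_outputs[cls] = str(outdir / f"stats_{cls}.tsv")

    # -- manifest
    manifest = {
        "seed": config.seed,
        "reference": ref_id,
        "parameters": {
            "simulation": _jsonable(asdict(config.simulation)),
            "scan": asdict(config.scan),
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
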