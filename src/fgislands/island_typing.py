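"""Typing of observed islands against built-in version signatures, marker
sequence clustering, and island-vs-genome AAI.

Gene recovery is label-based: the synthetic path carries exact
controlled-vocabulary annotations, and real-data annotations map through the
alias table in :mod:`fgislands.io_formats`.  Version scoring is the fraction
of a signature's required genes present in the island, with any forbidden
gene disqualifying the signature; ties break to the signature with the
larger required set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from skbio.tree import nj

from .io_formats import GeneFeature, SequenceRecord
from .island_scan import IslandCall
from .signatures import (
    CP_LYASE_MIN,
    PST_CORE,
    VersionSignature,
    signatures_for,
)

ASSIGN_MIN_SCORE = 0.8
AAI_MIN_IDENTITY = 30.0
AAI_MIN_COVERAGE = 0.70


# ---------------------------------------------------------------------------
# Gene extraction and version assignment
# ---------------------------------------------------------------------------

def extract_island_genes(island: IslandCall, features: Sequence[GeneFeature]
                         ) -> list[GeneFeature]:
    """Genes overlapping the island by at least 50% of their own length."""
    out = []
    for f in features:
        ov = min(island.end, f.end) - max(island.start, f.start)
        if ov > 0 and ov >= 0.5 * len(f):
            out.append(f)
    return out


@dataclass(frozen=True)
class VersionAssignment:
    island_class: str
    label: str
    score: float


def assign_version(genes: Iterable[str], island_class: str,
                   signatures: Mapping[str, VersionSignature] | None = None,
                   min_score: float = ASSIGN_MIN_SCORE) -> VersionAssignment:
    """Assign an island's gene set to the best-matching version signature.

    Partial (SAG-style) islands missing the class core — the pst operon for
    phosphate islands, the shared C-P lyase subset for phosphonate islands —
    are labelled "unassigned", as are gene sets scoring below ``min_score``.
    """
    gene_set = frozenset(genes)
    table = signatures if signatures is not None else signatures_for(island_class)

    core = set(PST_CORE) if island_class == "fGIp" else set(CP_LYASE_MIN)
    if island_class not in {"fGIp", "fGIphn"} and signatures is None:
        raise ValueError(f"unknown island class {island_class!r}")
    if not core <= gene_set:
        return VersionAssignment(island_class, "unassigned", 0.0)

    best: tuple[float, int, str] | None = None  # (score, |required|, label)
    for label, sig in table.items():
        if gene_set & set(sig.forbidden):
            continue
        score = len(gene_set & sig.required_set) / len(sig.required_set)
        key = (score, len(sig.required_set), label)
        if best is None or (key[0], key[1], [-ord(c) for c in key[2]]) > (
            best[0], best[1], [-ord(c) for c in best[2]]
        ):
            best = key
    if best is None or best[0] < min_score:
        return VersionAssignment(island_class, "unassigned", best[0] if best else 0.0)
    return VersionAssignment(island_class, best[2], best[0])


def carrier_prevalence(flags: Iterable[bool]) -> float:
    """Percentage of island-bearing genomes that carry a second island class."""
    flags = list(flags)
    if not flags:
        raise ValueError("empty membership table")
    return 100.0 * sum(bool(f) for f in flags) / len(flags)


# ---------------------------------------------------------------------------
# Pairwise protein/nucleotide identity
# ---------------------------------------------------------------------------

def _aligner(molecule: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if molecule == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    else:
        aligner.match_score = 2.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    return aligner


def global_identity(a: str, b: str, molecule: str = "protein"
                    ) -> tuple[float, float]:
    """(percent identity, coverage) from one global alignment.

    Identity is matches over aligned (both-non-gap) columns; coverage is
    aligned columns over the shorter sequence length.
    """
    if not a or not b:
        raise ValueError("cannot align zero-length sequence")
    aligner = _aligner(molecule)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches
    if aligned_cols == 0:
        return 0.0, 0.0
    identity = 100.0 * counts.identities / aligned_cols
    coverage = aligned_cols / min(len(a), len(b))
    return identity, coverage


# ---------------------------------------------------------------------------
# Marker-sequence clustering (PstS + PstC + PstA concatenations)
# ---------------------------------------------------------------------------

@dataclass
class MarkerClustering:
    #: representative id -> list of genome ids sharing the identical sequence
    dedup: dict[str, list[str]]
    #: representative id -> flat cluster label
    clusters: dict[str, int]
    newick: str
    distances: pd.DataFrame


def cluster_marker_sequences(
    marker_sets: Mapping[str, Mapping[str, str]],
    distance_cut: float = 0.05,
) -> MarkerClustering:
    """Cluster concatenated PstS+PstC+PstA marker sequences.

    ``marker_sets`` maps genome id -> {"pstS": seq, "pstC": seq, "pstA": seq}.
    Genomes missing a subunit are skipped with a warning.  Sequences are
    concatenated in the fixed order S, C, A, deduplicated at 100% identity,
    p-distances computed from global alignments, and a neighbour-joining
    tree emitted as newick alongside complete-linkage flat clusters at
    ``distance_cut``.
    """
    import logging

    logger = logging.getLogger(__name__)
    concat: dict[str, str] = {}
    for genome_id, subunits in marker_sets.items():
        missing = [s for s in ("pstS", "pstC", "pstA") if not subunits.get(s)]
        if missing:
            logger.warning("genome %s skipped: missing marker(s) %s",
                           genome_id, ",".join(missing))
            continue
        seq = subunits["pstS"] + subunits["pstC"] + subunits["pstA"]
        if not seq:
            raise ValueError(f"genome {genome_id}: zero-length marker sequence")
        concat[genome_id] = seq
    if not concat:
        raise ValueError("no genome with all three marker subunits")

    # dedupe at 100% identity; representative = first genome id (sorted)
    by_seq: dict[str, list[str]] = {}
    for gid in sorted(concat):
        by_seq.setdefault(concat[gid], []).append(gid)
    dedup = {members[0]: members for members in by_seq.values()}
    reps = sorted(dedup)

    n = len(reps)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident, _cov = global_identity(concat[reps[i]], concat[reps[j]],
                                          molecule="protein")
            dist[i, j] = dist[j, i] = 1.0 - ident / 100.0
    dist_df = pd.DataFrame(dist, index=reps, columns=reps)

    if n == 1:
        newick = f"{reps[0]};"
        clusters = {reps[0]: 1}
    elif n == 2:
        d = dist[0, 1]
        newick = f"({reps[0]}:{d / 2:.5f},{reps[1]}:{d / 2:.5f});"
        clusters = {r: (1 if dist[0, 1] <= distance_cut else i + 1)
                    for i, r in enumerate(reps)}
    else:
        tree = nj(DistanceMatrix(dist, ids=reps))
        newick = str(tree).strip()
        z = linkage(squareform(dist, checks=False), method="complete")
        flat = fcluster(z, t=distance_cut, criterion="distance")
        clusters = {r: int(c) for r, c in zip(reps, flat)}
    return MarkerClustering(dedup, clusters, newick, dist_df)


# ---------------------------------------------------------------------------
# AAI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AAIResult:
    set_a_id: str
    set_b_id: str
    aai: float | None
    n_bbh: int


def compute_aai(set_a: Sequence[SequenceRecord], set_b: Sequence[SequenceRecord],
                set_a_id: str = "A", set_b_id: str = "B") -> AAIResult:
    """AAI over bidirectional best hit protein pairs.

    BBH pairs require identity >= 30% and coverage of the shorter sequence
    >= 70%; AAI is the mean identity over qualifying pairs, None when no
    pair qualifies.
    """
    if not set_a or not set_b:
        raise ValueError("cannot compute AAI of an empty protein set")
    ident = np.zeros((len(set_a), len(set_b)))
    cover = np.zeros((len(set_a), len(set_b)))
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            ident[i, j], cover[i, j] = global_identity(a.sequence, b.sequence)
    best_ab = ident.argmax(axis=1)
    best_ba = ident.argmax(axis=0)
    identities = []
    for i, j in enumerate(best_ab):
        if best_ba[j] != i:
            continue
        if ident[i, j] >= AAI_MIN_IDENTITY and cover[i, j] >= AAI_MIN_COVERAGE:
            identities.append(ident[i, j])
    if not identities:
        return AAIResult(set_a_id, set_b_id, None, 0)
    return AAIResult(set_a_id, set_b_id, float(np.mean(identities)), len(identities))


def island_vs_genome_aai(paired: Mapping[str, tuple[float, float]]) -> pd.DataFrame:
    """Paired (island AAI, genome AAI) table feeding the signed-rank test."""
    if len(paired) < 2:
        raise ValueError("need at least 2 version pairs")
    rows = [
        {"version": v, "island_aai": ia, "genome_aai": ga}
        for v, (ia, ga) in sorted(paired.items())
    ]
    return pd.DataFrame(rows).set_index("version")
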