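"""Read recruitment against reference genomes: mapping, filtering, RPKG.

The internal mapper is a deliberately simple seed-and-extend, ungapped
aligner: exact k-mer seeds located through a genome index (both strands),
followed by full-read ungapped extension at each candidate offset.  Identity
is matches / read length.  It is adequate because the simulator emits
substitution-only reads; real-data users ingest BLAST tabular files instead
(``io_formats.read_blast_tab``) and everything downstream is shared.

Two identity tiers are used throughout: the species tier (alignment length
>= 50 nt and identity >= 98%, e-value <= 1e-5 where populated) gates
abundance and presence; the permissive tier (>= 50 nt, >= 70%) feeds linear
recruitment profiles.  All thresholds are inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import SequenceRecord, TabularAlignment
from .synthetic_community import reverse_complement

SPECIES_MIN_IDENTITY = 98.0
PERMISSIVE_MIN_IDENTITY = 70.0
MIN_ALIGN_LENGTH = 50
MAX_EVALUE = 1e-5
PRESENCE_MIN_RPKG = 10.0
PRESENCE_MIN_BREADTH = 0.60


# ---------------------------------------------------------------------------
# Genome index and mapper
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact k-mer index over a genome's forward strand."""

    def __init__(self, genome: SequenceRecord, k: int = 21):
        if len(genome.sequence) < k:
            raise ValueError(
                f"genome {genome.id} shorter than seed length {k}"
            )
        self.genome = genome
        self.k = k
        self.array = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
        seq = genome.sequence
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append(i)
        self._index = index

    def seed_positions(self, kmer: str) -> list[int]:
        return self._index.get(kmer, ())


def _candidate_starts(index: GenomeIndex, read: str) -> set[int]:
    k = index.k
    n = len(read)
    starts: set[int] = set()
    offsets = list(range(0, n - k + 1, k))
    if offsets and offsets[-1] != n - k:
        offsets.append(n - k)
    for off in offsets:
        for pos in index.seed_positions(read[off:off + k]):
            s = pos - off
            if 0 <= s <= len(index.array) - n:
                starts.add(s)
    return starts


def map_reads(reads: Iterable[SequenceRecord], genome: SequenceRecord,
              k: int = 21, min_identity: float = PERMISSIVE_MIN_IDENTITY,
              index: GenomeIndex | None = None) -> list[TabularAlignment]:
    """Map reads to a genome; one best ungapped hit per read.

    The best hit is the highest-identity candidate; ties break to the lowest
    genome coordinate, then to the forward strand.  Hits below
    ``min_identity`` are discarded.  The e-value field is not populated
    (NaN); downstream filters skip the e-value check in that case.
    """
    if index is None:
        index = GenomeIndex(genome, k=k)
    out: list[TabularAlignment] = []
    for read in reads:
        n = len(read.sequence)
        if n < index.k:
            continue
        best: tuple[float, int, int] | None = None  # (identity, start, strand_rank)
        for strand_rank, seq in enumerate(
            (read.sequence, reverse_complement(read.sequence))
        ):
            rarr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            for s in _candidate_starts(index, seq):
                matches = int(np.count_nonzero(index.array[s:s + n] == rarr))
                identity = matches / n * 100.0
                if best is None or (identity, -s, -strand_rank) > (
                    best[0], -best[1], -best[2]
                ):
                    best = (identity, s, strand_rank)
        if best is None or best[0] < min_identity:
            continue
        identity, s, strand_rank = best
        mismatches = n - int(round(identity / 100.0 * n))
        if strand_rank == 0:
            gstart, gend = s + 1, s + n
        else:
            gstart, gend = s + n, s + 1
        out.append(
            TabularAlignment(
                read_id=read.id, genome_id=genome.id,
                percent_identity=round(identity, 2), align_length=n,
                mismatches=mismatches, gap_opens=0,
                read_start=1, read_end=n,
                genome_start=gstart, genome_end=gend,
                evalue=float("nan"), bitscore=2.0 * (n - mismatches),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Filtering and normalisation
# ---------------------------------------------------------------------------

def filter_alignments(alignments: Iterable[TabularAlignment], tier: str
                      ) -> list[TabularAlignment]:
    """Keep alignments passing a named identity tier (thresholds inclusive)."""
    if tier == "species":
        return [
            a for a in alignments
            if a.align_length >= MIN_ALIGN_LENGTH
            and a.percent_identity >= SPECIES_MIN_IDENTITY
            and (math.isnan(a.evalue) or a.evalue <= MAX_EVALUE)
        ]
    if tier == "permissive":
        return [
            a for a in alignments
            if a.align_length >= MIN_ALIGN_LENGTH
            and a.percent_identity >= PERMISSIVE_MIN_IDENTITY
        ]
    raise ValueError(f"unknown tier {tier!r}; expected 'species' or 'permissive'")


def compute_rpkg(n_reads: int, genome_length: int, metagenome_size: int) -> float:
    """Reads per kb of genome per Gb of metagenome."""
    if genome_length <= 0:
        raise ValueError("genome length must be > 0")
    if metagenome_size <= 0:
        raise ValueError("metagenome size must be > 0")
    return n_reads / (genome_length / 1e3) / (metagenome_size / 1e9)


def coverage_profile(alignments: Sequence[TabularAlignment], genome_length: int
                     ) -> tuple[np.ndarray, float]:
    """Per-position read depth and breadth from one tier of alignments."""
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    for a in alignments:
        lo, hi = a.genome_interval()
        if lo < 0 or hi > genome_length:
            raise ValueError(
                f"alignment {a.read_id} [{lo}, {hi}) beyond genome end "
                f"{genome_length}"
            )
        diff[lo] += 1
        diff[hi] -= 1
    depth = np.cumsum(diff[:-1])
    breadth = float(np.count_nonzero(depth) / genome_length)
    return depth, breadth


@dataclass
class RecruitmentProfile:
    """Recruitment of one genome in one metagenome at both identity tiers."""

    genome_id: str
    sample_id: str
    depth98: np.ndarray
    depth70: np.ndarray
    n_reads98: int
    rpkg: float
    breadth98: float
    metagenome_size: int

    @property
    def genome_length(self) -> int:
        return len(self.depth98)


@dataclass(frozen=True)
class PresenceCall:
    genome_id: str
    sample_id: str
    present: bool
    rpkg: float
    breadth98: float


def call_presence(profile: RecruitmentProfile) -> PresenceCall:
    """Presence: RPKG >= 10 and species-tier breadth >= 0.60 (inclusive)."""
    present = (
        profile.rpkg >= PRESENCE_MIN_RPKG
        and profile.breadth98 >= PRESENCE_MIN_BREADTH
    )
    return PresenceCall(
        profile.genome_id, profile.sample_id, present,
        profile.rpkg, profile.breadth98,
    )


def recruit(reads: Sequence[SequenceRecord], genome: SequenceRecord,
            sample_id: str, k: int = 21,
            alignments: Sequence[TabularAlignment] | None = None,
            metagenome_size: int | None = None,
            index: GenomeIndex | None = None) -> RecruitmentProfile:
    """Full recruitment of one sample against one genome.

    ``alignments`` may carry precomputed (e.g. BLAST tabular) hits, in which
    case the internal mapper is skipped; ``metagenome_size`` (total bases in
    the read set) must then be given explicitly.
    """
    if alignments is None:
        alignments = map_reads(reads, genome, k=k, index=index)
    if metagenome_size is None:
        if not reads:
            raise ValueError("metagenome_size required when no reads are given")
        metagenome_size = sum(len(r.sequence) for r in reads)
    species = filter_alignments(alignments, "species")
    permissive = filter_alignments(alignments, "permissive")
    glen = len(genome.sequence)
    depth98, breadth98 = coverage_profile(species, glen)
    depth70, _ = coverage_profile(permissive, glen)
    rpkg = compute_rpkg(len(species), glen, metagenome_size)
    return RecruitmentProfile(
        genome_id=genome.id, sample_id=sample_id,
        depth98=depth98, depth70=depth70,
        n_reads98=len(species), rpkg=rpkg, breadth98=breadth98,
        metagenome_size=metagenome_size,
    )
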