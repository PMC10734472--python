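"""Metagenomic island delimitation from dual-tier recruitment profiles.

Islands are depleted stretches of the species-tier depth profile: sliding
windows whose mean depth falls below a fraction of the genome-wide median
window depth are merged (bridging short gaps), trimmed to base resolution
against the same threshold, and filtered by a minimum length.  Candidate
intervals from different samples are unified into loci by reciprocal
overlap, and each locus is classified conserved (flagged in every sample
where the genome is present) or variable.

The source study delimits islands visually from recruitment plots; the
window/step/alpha/beta/bridge/min-length parameters operationalize that and
are all configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GeneFeature
from .recruitment import PresenceCall, RecruitmentProfile


@dataclass(frozen=True)
class ScanParams:
    window: int = 1000
    step: int = 500
    depletion_alpha: float = 0.2
    bridge_gap: int = 2000
    min_island_length: int = 5000
    presence_beta: float = 0.5
    refine_search: int = 2000

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ValueError("step must be <= window")
        if not (0 < self.depletion_alpha < self.presence_beta <= 1):
            raise ValueError("require 0 < alpha < beta <= 1")


@dataclass
class CandidateIsland:
    genome_id: str
    sample_id: str
    start: int
    end: int
    depletion_score: float
    mean_depth98: float
    mean_depth70: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class IslandCall:
    genome_id: str
    start: int
    end: int
    locus_label: str
    #: sample_id -> "flagged" | "not-flagged" | "genome-absent"
    per_sample_flag: dict[str, str] = field(default_factory=dict)
    category: str = "variable"  # "conserved" | "variable"
    depletion_score: float = 0.0

    def __len__(self) -> int:
        return self.end - self.start


def _window_means(depth: np.ndarray, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean depth per sliding window; returns (starts, means)."""
    n = len(depth)
    if n < window:
        return np.array([0]), np.array([float(depth.mean())])
    csum = np.concatenate([[0], np.cumsum(depth)])
    starts = np.arange(0, n - window + 1, step)
    means = (csum[starts + window] - csum[starts]) / window
    return starts, means


def detect_islands(profile: RecruitmentProfile, params: ScanParams = ScanParams(),
                   presence: PresenceCall | None = None) -> list[CandidateIsland]:
    """Find depleted intervals in one sample's species-tier depth profile."""
    if presence is not None and not presence.present:
        raise ValueError(
            f"genome {profile.genome_id} absent in sample {profile.sample_id}; "
            "skip island detection for this sample"
        )
    depth = profile.depth98
    starts, means = _window_means(depth, params.window, params.step)
    median = float(np.median(means))
    if median <= 0:
        return []
    threshold = params.depletion_alpha * median
    flagged = means < threshold

    # merge flagged windows, bridging unflagged gaps <= bridge_gap
    intervals: list[list[int]] = []
    for s, f in zip(starts, flagged):
        if not f:
            continue
        w_end = min(int(s) + params.window, len(depth))
        if intervals and int(s) - intervals[-1][1] <= params.bridge_gap:
            intervals[-1][1] = w_end
        else:
            intervals.append([int(s), w_end])

    out: list[CandidateIsland] = []
    for s, e in intervals:
        s, e = _trim_to_base_resolution(depth, s, e, threshold)
        if e - s < params.min_island_length:
            continue
        mean98 = float(depth[s:e].mean())
        mean70 = float(profile.depth70[s:e].mean())
        score = min(1.0, max(0.0, 1.0 - mean98 / median))
        out.append(
            CandidateIsland(profile.genome_id, profile.sample_id, s, e,
                            score, mean98, mean70)
        )
    return out


def _trim_to_base_resolution(depth: np.ndarray, start: int, end: int,
                             threshold: float) -> tuple[int, int]:
    """Refine window-grid edges against the per-base depth.

    Extends each edge outward while per-base depth stays below the depletion
    threshold and trims it inward otherwise, so boundaries land within about
    a read length of the true depleted region rather than on the window grid.
    """
    while start > 0 and depth[start - 1] < threshold:
        start -= 1
    while start < end and depth[start] >= threshold:
        start += 1
    while end < len(depth) and depth[end] < threshold:
        end += 1
    while end > start and depth[end - 1] >= threshold:
        end -= 1
    return start, end


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """True when intervals overlap by >= 50% of each interval's length."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    ov = hi - lo
    return ov > 0 and ov >= 0.5 * (a[1] - a[0]) and ov >= 0.5 * (b[1] - b[0])


def classify_islands(
    candidates_by_sample: Mapping[str, Sequence[CandidateIsland]],
    presence_calls: Mapping[str, PresenceCall],
    profiles: Mapping[str, RecruitmentProfile],
    params: ScanParams = ScanParams(),
) -> list[IslandCall]:
    """Unify per-sample candidates into loci and classify them.

    Loci are connected components of the reciprocal-50% overlap relation
    across samples.  A locus is flagged in a sample when one of that
    sample's candidates overlaps it; it is conserved when flagged in every
    sample where the genome is present.  In non-flagged present samples the
    island interval must recruit at least ``presence_beta`` of the median
    window depth to be counted as covered (recorded as "not-flagged").
    """
    present_samples = [s for s, c in presence_calls.items() if c.present]
    if not present_samples:
        raise ValueError("no samples with the genome present")

    pool: list[CandidateIsland] = [
        c for s in present_samples for c in candidates_by_sample.get(s, [])
    ]
    if not pool:
        return []
    genome_id = pool[0].genome_id

    # single-linkage components under reciprocal overlap
    pool.sort(key=lambda c: (c.start, c.end))
    parent = list(range(len(pool)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            if pool[j].start >= pool[i].end:
                break
            if _reciprocal_overlap(
                (pool[i].start, pool[i].end), (pool[j].start, pool[j].end)
            ):
                parent[find(i)] = find(j)

    groups: dict[int, list[CandidateIsland]] = {}
    for i, c in enumerate(pool):
        groups.setdefault(find(i), []).append(c)

    calls: list[IslandCall] = []
    for members in groups.values():
        start = int(np.median([m.start for m in members]))
        end = int(np.median([m.end for m in members]))
        flags: dict[str, str] = {}
        for sample_id, pc in presence_calls.items():
            if not pc.present:
                flags[sample_id] = "genome-absent"
                continue
            hit = any(
                _reciprocal_overlap((start, end), (c.start, c.end))
                for c in candidates_by_sample.get(sample_id, [])
            )
            if hit:
                flags[sample_id] = "flagged"
            else:
                # require real coverage of the locus to count the island as
                # present in this sample's population
                prof = profiles[sample_id]
                _, means = _window_means(prof.depth98, params.window, params.step)
                median = float(np.median(means))
                island_mean = float(prof.depth98[start:end].mean())
                flags[sample_id] = "not-flagged"
                if median > 0 and island_mean < params.presence_beta * median:
                    flags[sample_id] = "flagged"
        n_flagged = sum(1 for s in present_samples if flags[s] == "flagged")
        category = "conserved" if n_flagged == len(present_samples) else "variable"
        score = float(np.mean([m.depletion_score for m in members]))
        calls.append(
            IslandCall(genome_id, start, end, locus_label="",
                       per_sample_flag=flags, category=category,
                       depletion_score=score)
        )

    calls.sort(key=lambda c: c.start)
    # resolve any residual overlap between loci and assign labels
    for i, call in enumerate(calls):
        if i and call.start < calls[i - 1].end:
            call.start = calls[i - 1].end
        call.locus_label = f"{genome_id}_MI{i + 1:02d}"
    return [c for c in calls if c.end > c.start]


def refine_boundaries(island: IslandCall, features: Sequence[GeneFeature],
                      params: ScanParams = ScanParams()) -> IslandCall:
    """Snap island edges to the nearest conserved-gene boundary.

    The start snaps to the closest gene end within the search range (leaving
    that gene wholly outside the island), the end to the closest gene start;
    edges stay unchanged when no gene boundary lies within range.
    """
    search = params.refine_search
    start, end = island.start, island.end

    ends = [f.end for f in features if abs(f.end - start) <= search]
    if ends:
        new_start = min(ends, key=lambda e: abs(e - start))
        if new_start < end:
            start = new_start
    starts = [f.start for f in features if abs(f.start - end) <= search]
    if starts:
        new_end = min(starts, key=lambda s: abs(s - end))
        if new_end > start:
            end = new_end

    return IslandCall(
        island.genome_id, start, end, island.locus_label,
        dict(island.per_sample_flag), island.category, island.depletion_score,
    )


def scan_genome(
    profiles: Mapping[str, RecruitmentProfile],
    presence_calls: Mapping[str, PresenceCall],
    features: Sequence[GeneFeature] | None = None,
    params: ScanParams = ScanParams(),
) -> list[IslandCall]:
    """Detect, classify and refine islands for one genome across samples."""
    candidates = {
        sample_id: detect_islands(prof, params)
        for sample_id, prof in profiles.items()
        if presence_calls[sample_id].present
    }
    calls = classify_islands(candidates, presence_calls, profiles, params)
    if features:
        calls = [refine_boundaries(c, features, params) for c in calls]
    return calls
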