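"""Fragment-based ANI, dereplication and genomospecies assignment.

ANI follows the ANIb convention: the query is cut into consecutive 1,020 nt
fragments, each mapped against the subject (permissive, ungapped mapper);
fragments are accepted at >= 30% identity and >= 70% aligned fraction, and
ANI is the mean identity over accepted fragments.  Species clusters are
single-linkage components at ANI >= 95; dereplication uses > 99.
Genomospecies combine the species cluster with a distribution group obtained
by complete-linkage clustering of per-sample RPKG profiles (1 - Spearman
correlation, cut at correlation 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .io_formats import SequenceRecord
from .recruitment import GenomeIndex, map_reads

ANI_FRAGMENT_LENGTH = 1020
ANI_MIN_IDENTITY = 30.0
ANI_MIN_ALIGNED_FRACTION = 0.70
SPECIES_ANI_THRESHOLD = 95.0
DEREPLICATION_ANI_THRESHOLD = 99.0
DISTRIBUTION_MIN_CORRELATION = 0.7


@dataclass(frozen=True)
class ANIResult:
    query_id: str
    subject_id: str
    ani: float | None
    aligned_fraction: float


@dataclass(frozen=True)
class GenomospeciesAssignment:
    genome_id: str
    species_cluster: int
    genomospecies: str
    representative: bool


def compute_ani(query: SequenceRecord, subject: SequenceRecord,
                fragment_length: int = ANI_FRAGMENT_LENGTH,
                k: int = 14,
                subject_index: GenomeIndex | None = None) -> ANIResult:
    """Fragment-based ANI of ``query`` against ``subject``."""
    if len(query.sequence) < fragment_length:
        raise ValueError(
            f"query {query.id} shorter than one fragment ({fragment_length} nt)"
        )
    if len(subject.sequence) < fragment_length:
        raise ValueError(
            f"subject {subject.id} shorter than one fragment ({fragment_length} nt)"
        )
    fragments = [
        SequenceRecord(f"{query.id}|frag{i}", query.sequence[s:s + fragment_length])
        for i, s in enumerate(range(0, len(query.sequence) - fragment_length + 1,
                                    fragment_length))
    ]
    if subject_index is None:
        subject_index = GenomeIndex(subject, k=k)
    hits = map_reads(fragments, subject, k=k, min_identity=0.0,
                     index=subject_index)
    identities = []
    for h in hits:
        aligned = h.align_length / fragment_length
        if h.percent_identity >= ANI_MIN_IDENTITY and aligned >= ANI_MIN_ALIGNED_FRACTION:
            identities.append(h.percent_identity)
    if not identities:
        return ANIResult(query.id, subject.id, None, 0.0)
    return ANIResult(
        query.id, subject.id, float(np.mean(identities)),
        len(identities) / len(fragments),
    )


def ani_matrix(genomes: Sequence[SequenceRecord],
               fragment_length: int = ANI_FRAGMENT_LENGTH,
               k: int = 14) -> pd.DataFrame:
    """Symmetrised pairwise ANI (mean of the two directions); NaN when unalignable."""
    ids = [g.id for g in genomes]
    indexes = {g.id: GenomeIndex(g, k=k) for g in genomes}
    mat = pd.DataFrame(np.full((len(ids), len(ids)), np.nan), index=ids, columns=ids)
    for g in genomes:
        mat.loc[g.id, g.id] = 100.0
    for i, a in enumerate(genomes):
        for b in genomes[i + 1:]:
            fwd = compute_ani(a, b, fragment_length, k, subject_index=indexes[b.id])
            rev = compute_ani(b, a, fragment_length, k, subject_index=indexes[a.id])
            vals = [r.ani for r in (fwd, rev) if r.ani is not None]
            if vals:
                mat.loc[a.id, b.id] = mat.loc[b.id, a.id] = float(np.mean(vals))
    return mat


def _components(ids: Sequence[str], linked) -> dict[str, int]:
    """Single-linkage connected components; linked(a, b) -> bool."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if linked(a, b):
                parent[find(a)] = find(b)
    roots: dict[str, int] = {}
    out = {}
    for i in ids:
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        out[i] = roots[r]
    return out


def dereplicate(genomes: Sequence[SequenceRecord],
                ani: pd.DataFrame | None = None,
                ani_threshold: float = DEREPLICATION_ANI_THRESHOLD
                ) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Single-linkage dereplication at ANI > threshold.

    The representative of each component is the member with the greatest
    ungapped length (completeness proxy); ties break to the
    lexicographically smallest id.  Returns (representatives, member ->
    representative map).
    """
    if ani is None:
        ani = ani_matrix(genomes)
    by_id = {g.id: g for g in genomes}
    ids = [g.id for g in genomes]

    comp = _components(
        ids,
        lambda a, b: pd.notna(ani.loc[a, b]) and ani.loc[a, b] > ani_threshold,
    )
    members: dict[int, list[str]] = {}
    for gid, c in comp.items():
        members.setdefault(c, []).append(gid)
    mapping: dict[str, str] = {}
    reps: list[SequenceRecord] = []
    for grp in members.values():
        rep = sorted(grp, key=lambda g: (-len(by_id[g].sequence), g))[0]
        reps.append(by_id[rep])
        for gid in grp:
            mapping[gid] = rep
    reps.sort(key=lambda g: g.id)
    return reps, mapping


def assign_genomospecies(
    representatives: Sequence[str],
    ani: pd.DataFrame,
    rpkg: pd.DataFrame,
    presence: pd.DataFrame | None = None,
) -> list[GenomospeciesAssignment]:
    """Combine ANI clusters with distribution patterns into genomospecies.

    ``rpkg`` is genomes x samples.  ``presence`` (same shape, boolean) marks
    samples where each genome passes the presence rule; genomes present
    nowhere are labelled "unclassified".  Within each ANI >= 95 species
    cluster, genomes are grouped by complete-linkage clustering on
    1 - Spearman correlation of their RPKG profiles, cut at correlation 0.7.
    """
    if rpkg.empty:
        raise ValueError("empty RPKG matrix")
    ids = list(representatives)
    comp = _components(
        ids,
        lambda a, b: pd.notna(ani.loc[a, b]) and ani.loc[a, b] >= SPECIES_ANI_THRESHOLD,
    )
    if presence is None:
        presence = rpkg > 0

    out: list[GenomospeciesAssignment] = []
    clusters: dict[int, list[str]] = {}
    for gid in ids:
        clusters.setdefault(comp[gid], []).append(gid)

    for cluster_id in sorted(clusters):
        grp = sorted(clusters[cluster_id])
        classified = [g for g in grp if bool(presence.loc[g].any())]
        for g in grp:
            if g not in classified:
                out.append(GenomospeciesAssignment(g, cluster_id, "unclassified", False))
        if not classified:
            continue
        if len(classified) == 1:
            labels = {classified[0]: 1}
        else:
            profiles = rpkg.loc[classified].to_numpy(dtype=float)
            n = len(classified)
            dist = np.zeros((n, n))
            import warnings

            for i in range(n):
                for j in range(i + 1, n):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        rho = spearmanr(profiles[i], profiles[j]).statistic
                    if np.isnan(rho):
                        rho = 0.0
                    dist[i, j] = dist[j, i] = 1.0 - rho
            z = linkage(squareform(dist, checks=False), method="complete")
            flat = fcluster(z, t=1.0 - DISTRIBUTION_MIN_CORRELATION,
                            criterion="distance")
            labels = {g: int(c) for g, c in zip(classified, flat)}
        # stable letters in order of first appearance
        seen: dict[int, str] = {}
        for g in classified:
            c = labels[g]
            if c not in seen:
                seen[c] = chr(ord("A") + len(seen))
            out.append(
                GenomospeciesAssignment(g, cluster_id, f"{cluster_id}.{seen[c]}", True)
            )
    out.sort(key=lambda a: a.genome_id)
    return out
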