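"""Three-stage detection of mutation clusters in densely mutagenized genomes.

Stage 1 — per-chromosome UPGMA (average linkage) hierarchical clustering of
SNV coordinates, then flat-cluster extraction by a cophenetic-distance
criterion (default 1000 bp): every SNV pair within an extracted cluster joins
below the threshold.

Stage 2 — each extracted cluster is re-clustered from scratch and its borders
adjusted by splitting dendrogram links whose inconsistency coefficient
exceeds a threshold (default 0.8 at depth 2).

Stage 3 — filtering: clusters touching masked regions are dropped; in
deaminase mode clusters with more than one non-deaminase-like (OTHER) SNV are
dropped, while a single OTHER SNV confined to one sample is deleted from the
cluster; finally size >= 5 and power >= 0.05 cutoffs apply (inclusive).

UPGMA on 1-D coordinates has a useful specialization: the average distance
between two disjoint contiguous clusters on the line equals the difference of
their means, so merges always join adjacent blocks. The implementation below
exploits this (O(n^2), deterministic, leftmost tie-break) and emits a
scipy-format linkage matrix so scipy's cophenet/fcluster operate on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy

from . import metrics
from .io import MaskSet, MutationClass, PooledVariantSet, SnvRecord


@dataclass
class ClusterParams:
    """Knobs of the detection cascade, defaulting to the published settings."""

    cophenetic_threshold: float = 1000.0  # bp
    inconsistency_threshold: float = 0.8
    inconsistency_depth: int = 2
    min_size: int = 5
    min_power: float = 0.05  # per bp
    max_nondeaminase: int = 1
    power_gap_mode: str = "consecutive"  # or "allpairs"
    refinement_statistic: str = "relative"  # or "standard"

    def __post_init__(self):
        if self.cophenetic_threshold <= 0:
            raise ValueError("cophenetic_threshold must be > 0")
        if self.min_size < 1 or self.min_power < 0:
            raise ValueError("min_size >= 1 and min_power >= 0 required")


@dataclass
class Dendrogram:
    """UPGMA merge tree over sorted 1-D SNV coordinates.

    ``linkage`` is a scipy-format matrix (left id, right id, height bp,
    member count); leaves are indices into ``positions``.
    """

    positions: np.ndarray
    linkage: np.ndarray  # shape (n-1, 4); empty for a single leaf

    @property
    def n_leaves(self) -> int:
        return len(self.positions)

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance matrix (scipy pdist ordering)."""
        if self.n_leaves < 2:
            return np.zeros(0)
        return hierarchy.cophenet(self.linkage)

    def flat_clusters(self, t: float) -> list[np.ndarray]:
        """Tree cut at height t: maximal subtrees whose root merge height is
        <= t, i.e. every within-cluster pair has cophenetic distance <= t.
        Returned as leaf-index arrays ordered by position."""
        if t <= 0:
            raise ValueError("threshold must be > 0")
        if self.n_leaves == 1:
            return [np.array([0])]
        labels = hierarchy.fcluster(self.linkage, t=t, criterion="distance")
        out: dict[int, list[int]] = {}
        for leaf, lab in enumerate(labels):
            out.setdefault(lab, []).append(leaf)
        return sorted((np.asarray(v) for v in out.values()), key=lambda a: a[0])


def upgma_linkage(positions: Sequence[float]) -> Dendrogram:
    """UPGMA dendrogram of 1-D coordinates.

    The distance between clusters u and v is the mean over all cross pairs
    |u_i - v_j|; for disjoint 1-D blocks this is |mean(u) - mean(v)|, so the
    globally closest pair is always adjacent in coordinate order. Ties merge
    the leftmost pair.
    """
    pos = np.sort(np.asarray(positions, dtype=float))
    n = len(pos)
    if n == 0:
        raise ValueError("upgma_linkage requires at least one position")
    if n == 1:
        return Dendrogram(pos, np.zeros((0, 4)))
    means = pos.copy()
    counts = np.ones(n, dtype=np.int64)
    ids = np.arange(n, dtype=np.int64)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        gaps = means[1:] - means[:-1]
        k = int(np.argmin(gaps))  # leftmost minimal gap
        h = float(gaps[k])
        cnt = counts[k] + counts[k + 1]
        merged_mean = (means[k] * counts[k] + means[k + 1] * counts[k + 1]) / cnt
        Z[step] = (ids[k], ids[k + 1], h, cnt)
        means[k] = merged_mean
        counts[k] = cnt
        ids[k] = n + step
        means = np.delete(means, k + 1)
        counts = np.delete(counts, k + 1)
        ids = np.delete(ids, k + 1)
    return Dendrogram(pos, Z)


def extract_flat_clusters(dendrogram: Dendrogram, t: float) -> list[np.ndarray]:
    """Distance-criterion extraction (tree cut at cophenetic distance t)."""
    return dendrogram.flat_clusters(t)


# ---------------------------------------------------------------------------
# Stage 2: inconsistency-based refinement
# ---------------------------------------------------------------------------

def _link_heights(Z: np.ndarray, node: int, depth: int, n: int, acc: list[float]) -> None:
    # collect heights of `node` and descendant links fewer than `depth` levels
    # below it
    if node < n or depth <= 0:
        return
    row = Z[node - n]
    acc.append(float(row[2]))
    _link_heights(Z, int(row[0]), depth - 1, n, acc)
    _link_heights(Z, int(row[1]), depth - 1, n, acc)


def link_inconsistency(Z: np.ndarray, node: int, depth: int, n: int) -> float:
    """Textbook inconsistency coefficient: (h - mean(H)) / sd(H) with H the
    heights of the link and descendant links within `depth` levels
    (population sd; 0 when sd is 0).

    Note this statistic is scale-free: with the two or three heights a
    depth-2 neighborhood holds, any link standing above two comparable
    children scores ~1.0-1.41 whether the height jump is 1.5-fold or
    100-fold, so it separates tree shapes, not distance scales.
    """
    acc: list[float] = []
    _link_heights(Z, node, depth, n, acc)
    h = float(Z[node - n][2])
    mean = float(np.mean(acc))
    sd = float(np.std(acc))  # population sd (ddof=0)
    if sd == 0:
        return 0.0
    return (h - mean) / sd


def link_relative_excess(Z: np.ndarray, node: int, depth: int, n: int) -> float:
    """Scale-aware link statistic for border adjustment: the excess of a
    link's height over the average height of its descendant links within
    `depth` levels, as a fraction of the link height — i.e.
    1 - mean(descendants)/h, in [0, 1). 0 when the link has no descendant
    links (both children are leaves)."""
    acc: list[float] = []
    row = Z[node - n]
    _link_heights(Z, int(row[0]), depth - 1, n, acc)
    _link_heights(Z, int(row[1]), depth - 1, n, acc)
    h = float(row[2])
    if not acc or h == 0:
        return 0.0
    return (h - float(np.mean(acc))) / h


def _leaves_below(Z: np.ndarray, node: int, n: int) -> list[int]:
    if node < n:
        return [node]
    row = Z[node - n]
    return _leaves_below(Z, int(row[0]), n) + _leaves_below(Z, int(row[1]), n)


def refine_by_inconsistency(positions: Sequence[float], threshold: float = 0.8,
                            depth: int = 2, statistic: str = "relative",
                            ) -> list[np.ndarray]:
    """Adjust cluster borders: re-cluster the members from scratch, then walk
    the fresh tree top-down, splitting any link whose inconsistency exceeds
    the threshold and emitting the leaves of consistent links as one
    subcluster each. Returns index arrays partitioning the input (coordinate
    order). Clusters of size <= 2 are returned unchanged.

    ``statistic='relative'`` (default) compares a link's height against the
    average height of the links beneath it on the scale of the link itself
    (see :func:`link_relative_excess`), so a link splits only when it stands
    far above its local neighborhood — single-scale dense clusters pass
    through unchanged while stragglers and multi-block composites are cut.
    ``statistic='standard'`` uses the textbook dispersion-standardized
    coefficient (:func:`link_inconsistency`), which at the same threshold
    splits any balanced link regardless of the height ratio.
    """
    pos = np.sort(np.asarray(positions, dtype=float))
    n = len(pos)
    if n == 0:
        return []
    if n <= 2:
        return [np.arange(n)]
    stat = {"relative": link_relative_excess,
            "standard": link_inconsistency}[statistic]
    dend = upgma_linkage(pos)
    Z = dend.linkage
    out: list[np.ndarray] = []
    stack = [2 * n - 2]  # root id
    while stack:
        node = stack.pop()
        if node >= n and stat(Z, node, depth, n) > threshold:
            row = Z[node - n]
            stack.append(int(row[1]))
            stack.append(int(row[0]))
        else:
            out.append(np.asarray(sorted(_leaves_below(Z, node, n))))
    return sorted(out, key=lambda a: a[0])


# ---------------------------------------------------------------------------
# Cluster objects and stage 3 filtering
# ---------------------------------------------------------------------------

@dataclass
class MutationCluster:
    """A detected cluster with its descriptive statistics."""

    cluster_id: str
    chrom: str
    members: list[SnvRecord]
    start: int = 0
    end: int = 0
    span: int = 0
    size: int = 0
    power: float = 0.0
    homogeneity: Optional[float] = None
    majority_class: Optional[str] = None

    def __post_init__(self):
        if not self.members:
            raise ValueError("cluster has no members")
        self.recompute()

    def recompute(self, gap_mode: str = "consecutive") -> None:
        self.members.sort(key=lambda r: r.pos)
        self.start = self.members[0].pos
        self.end = self.members[-1].pos
        self.span = self.end - self.start
        self.size = len(self.members)
        self.power = metrics.cluster_power(self.members, gap_mode=gap_mode)
        self.homogeneity = metrics.cluster_homogeneity(self.members)
        self.majority_class = metrics.majority_class(self.members)


@dataclass
class FilterReport:
    """What stage 3 removed and the per-sample restored SNV lists."""

    removed_clusters: list[tuple[MutationCluster, str]] = field(default_factory=list)
    removed_snvs: list[SnvRecord] = field(default_factory=list)
    restored_by_sample: dict[str, list[SnvRecord]] = field(default_factory=dict)
    n_input: int = 0
    n_kept: int = 0


def filter_clusters(clusters: Sequence[MutationCluster], masks: Optional[MaskSet],
                    params: ClusterParams, deaminase_mode: bool = True,
                    ) -> tuple[list[MutationCluster], FilterReport]:
    """Stage-3 filtering cascade.

    (a) drop clusters with any member in a masked region; (b) in deaminase
    mode drop clusters with more than ``max_nondeaminase`` OTHER members, and
    delete a lone OTHER member confined to a single sample; (c) recompute the
    statistics; (d) apply the inclusive size/power cutoffs; (e) restore
    per-sample SNV lists from everything surviving (a)-(b).
    """
    report = FilterReport(n_input=len(clusters))
    survivors: list[MutationCluster] = []
    for c in clusters:
        if masks is not None and any(masks.contains(c.chrom, m.pos) for m in c.members):
            report.removed_clusters.append((c, "masked"))
            continue
        if deaminase_mode:
            others = [m for m in c.members if m.mclass is MutationClass.OTHER]
            if len(others) > params.max_nondeaminase:
                report.removed_clusters.append((c, "nondeaminase"))
                continue
            if others:
                samples = {m.sample_id for m in others}
                if len(others) == 1 and len(samples) == 1:
                    c.members = [m for m in c.members if m.mclass is not MutationClass.OTHER]
                    report.removed_snvs.extend(others)
                    if not c.members:
                        report.removed_clusters.append((c, "empty_after_snv_removal"))
                        continue
                    c.recompute(gap_mode=params.power_gap_mode)
                elif len(samples) > 1:
                    # recurrence across samples is unexplained by a one-off
                    # call error; treat conservatively and drop
                    report.removed_clusters.append((c, "nondeaminase_multisample"))
                    continue
        survivors.append(c)
    for c in survivors:
        for m in c.members:
            report.restored_by_sample.setdefault(m.sample_id, []).append(m)
    kept: list[MutationCluster] = []
    for c in survivors:
        c.recompute(gap_mode=params.power_gap_mode)
        if c.size >= params.min_size and c.power >= params.min_power:
            kept.append(c)
        else:
            report.removed_clusters.append((c, "size_power"))
    report.n_kept = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def detect_clusters_full(pooled: PooledVariantSet, masks: Optional[MaskSet] = None,
                         params: Optional[ClusterParams] = None,
                         deaminase_mode: bool = True,
                         ) -> tuple[list[MutationCluster], FilterReport]:
    """extract -> refine -> filter, per chromosome; clusters never span
    chromosomes. Returns the kept clusters sorted by (chrom, start) plus the
    filtering report."""
    params = params or ClusterParams()
    candidates: list[MutationCluster] = []
    for chrom, records in sorted(pooled.by_chromosome().items()):
        positions = np.asarray([r.pos for r in records], dtype=float)
        dend = upgma_linkage(positions)
        # records sorted by pos already (pooled invariant); leaf i <-> records[i]
        for flat in extract_flat_clusters(dend, params.cophenetic_threshold):
            flat_records = [records[i] for i in flat]
            flat_pos = [r.pos for r in flat_records]
            for sub in refine_by_inconsistency(flat_pos, params.inconsistency_threshold,
                                               params.inconsistency_depth,
                                               statistic=params.refinement_statistic):
                members = [flat_records[i] for i in sub]
                candidates.append(MutationCluster(
                    cluster_id=f"{chrom}_{members[0].pos}", chrom=chrom,
                    members=members))
    kept, report = filter_clusters(candidates, masks, params, deaminase_mode)
    kept.sort(key=lambda c: (c.chrom, c.start))
    for i, c in enumerate(kept, start=1):
        c.cluster_id = f"cluster_{i:04d}"
    return kept, report


def detect_clusters(pooled: PooledVariantSet, masks: Optional[MaskSet] = None,
                    params: Optional[ClusterParams] = None,
                    deaminase_mode: bool = True) -> list[MutationCluster]:
    """Convenience wrapper around :func:`detect_clusters_full`."""
    kept, _ = detect_clusters_full(pooled, masks, params, deaminase_mode)
    return kept


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    thresholds: np.ndarray
    counts: np.ndarray        # clusters with >= min_count members
    total_counts: np.ndarray  # all flat clusters
    min_count: int = 3

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"threshold_bp": self.thresholds,
                             f"clusters_ge_{self.min_count}": self.counts,
                             "clusters_total": self.total_counts})


def threshold_sweep(pooled: PooledVariantSet, t_min: float = 50.0,
                    t_max: float = 5000.0, step: float = 50.0,
                    min_count: int = 3) -> SweepResult:
    """Count unrefined, unfiltered flat clusters with >= min_count members on
    a grid of extraction thresholds (used to pick the plateau threshold)."""
    if t_min <= 0:
        raise ValueError("t_min must be > 0")
    if len(pooled) == 0:
        raise ValueError("threshold_sweep requires a non-empty variant set")
    thresholds = np.arange(t_min, t_max + step / 2, step)
    dendros = [upgma_linkage([r.pos for r in recs])
               for recs in pooled.by_chromosome().values()]
    counts = np.zeros(len(thresholds), dtype=int)
    totals = np.zeros(len(thresholds), dtype=int)
    for i, t in enumerate(thresholds):
        for dend in dendros:
            flats = dend.flat_clusters(float(t))
            totals[i] += len(flats)
            counts[i] += sum(1 for f in flats if len(f) >= min_count)
    return SweepResult(thresholds, counts, totals, min_count=min_count)
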