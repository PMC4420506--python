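"""Cluster statistics: power, homogeneity, and summary grids/histograms.

Power is the cluster size divided by the median inter-SNV distance within the
cluster (per bp); homogeneity is the fraction of the cluster's deaminase-like
(CT/GA) members belonging to the majority class, so 1 means a fully
strand-polar cluster and 0.5 a perfectly mixed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import MutationClass, SnvRecord


def _positions(members) -> np.ndarray:
    if hasattr(members, "members"):
        members = members.members
    pos = [m.pos if isinstance(m, SnvRecord) else m for m in members]
    return np.sort(np.asarray(pos, dtype=float))


def cluster_power(members, gap_mode: str = "consecutive") -> float:
    """size / median inter-SNV distance.

    ``gap_mode='consecutive'`` (default) takes the median of consecutive gaps
    after sorting by position; ``'allpairs'`` uses all pairwise distances.
    Degenerate cases: a single-member cluster gets power = size (denominator
    1 bp); a zero median (duplicate positions) is clamped to 1 bp.
    """
    pos = _positions(members)
    n = len(pos)
    if n == 0:
        raise ValueError("empty cluster")
    if n == 1:
        return float(n)
    if gap_mode == "consecutive":
        gaps = np.diff(pos)
    elif gap_mode == "allpairs":
        gaps = np.abs(pos[:, None] - pos[None, :])[np.triu_indices(n, k=1)]
    else:
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    med = float(np.median(gaps))
    if med == 0:
        med = 1.0
    return n / med


def class_counts(members) -> tuple[int, int, int]:
    """(n_CT, n_GA, n_OTHER) for a cluster or record iterable."""
    if hasattr(members, "members"):
        members = members.members
    n_ct = n_ga = n_other = 0
    for m in members:
        if m.mclass is MutationClass.CT:
            n_ct += 1
        elif m.mclass is MutationClass.GA:
            n_ga += 1
        else:
            n_other += 1
    return n_ct, n_ga, n_other


def cluster_homogeneity(members) -> Optional[float]:
    """max(nCT, nGA) / (nCT + nGA); OTHER members are excluded.

    Undefined (None) for clusters with no CT/GA member.
    """
    n_ct, n_ga, _ = class_counts(members)
    if n_ct + n_ga == 0:
        return None
    return max(n_ct, n_ga) / (n_ct + n_ga)


def majority_class(members) -> Optional[str]:
    """'CT', 'GA', 'tie', or None when no CT/GA member exists."""
    n_ct, n_ga, _ = class_counts(members)
    if n_ct + n_ga == 0:
        return None
    if n_ct == n_ga:
        return "tie"
    return "CT" if n_ct > n_ga else "GA"


@dataclass
class ClusterSummaryGrid:
    """2-D histogram of cluster counts over (size, power-or-homogeneity)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # shape (len(x_edges)-1, len(y_edges)-1)
    x_label: str = "size"
    y_label: str = "power"

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        import pandas as pd

        idx = [f"[{self.x_edges[i]:g},{self.x_edges[i+1]:g})"
               for i in range(len(self.x_edges) - 1)]
        cols = [f"[{self.y_edges[j]:g},{self.y_edges[j+1]:g})"
                for j in range(len(self.y_edges) - 1)]
        return pd.DataFrame(self.counts.astype(int), index=idx, columns=cols)


def _default_size_edges(sizes: np.ndarray) -> np.ndarray:
    lo = int(sizes.min())
    hi = int(np.percentile(sizes, 95))
    edges = np.arange(lo, max(hi, lo + 1) + 1, 1, dtype=float)
    top = sizes.max() + 1
    if top > edges[-1]:
        edges = np.append(edges, top)  # open-ended top bin
    return edges


def summarize_grid(clusters: Sequence, y: str = "power",
                   x_edges=None, y_edges=None) -> ClusterSummaryGrid:
    """Count clusters in (size x power) or (size x homogeneity) cells.

    Clusters with an undefined y value (e.g. homogeneity of an all-OTHER
    cluster) are dropped from the grid. Bin edges default to unit-width size
    bins up to the 95th percentile (then one open-ended bin) and a log-spaced
    power grid or ten linear homogeneity bins over [0.5, 1].
    """
    pairs = [(c.size, getattr(c, y)) for c in clusters if getattr(c, y) is not None]
    if not pairs:
        xe = np.asarray(x_edges if x_edges is not None else [0.0, 1.0], dtype=float)
        ye = np.asarray(y_edges if y_edges is not None else [0.0, 1.0], dtype=float)
        return ClusterSummaryGrid(xe, ye, np.zeros((len(xe) - 1, len(ye) - 1)),
                                  y_label=y)
    sizes = np.asarray([p[0] for p in pairs], dtype=float)
    yvals = np.asarray([p[1] for p in pairs], dtype=float)
    if x_edges is None:
        x_edges = _default_size_edges(sizes)
    if y_edges is None:
        if y == "homogeneity":
            y_edges = np.linspace(0.5, 1.0, 11)
        else:
            lo = max(yvals.min(), 1e-3)
            y_edges = np.geomspace(lo, max(yvals.max() * 1.001, lo * 10), 13)
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    # np.histogram2d excludes values above the top edge; clip into range so
    # the grid conserves the cluster count
    sizes = np.clip(sizes, x_edges[0], np.nextafter(x_edges[-1], -np.inf))
    yvals = np.clip(yvals, y_edges[0], np.nextafter(y_edges[-1], -np.inf))
    counts, _, _ = np.histogram2d(sizes, yvals, bins=[x_edges, y_edges])
    return ClusterSummaryGrid(x_edges, y_edges, counts, y_label=y)


def length_distribution(clusters: Sequence, bin_width: int = 100):
    """Histogram of cluster spans in [k*bin, (k+1)*bin) bins.

    Returns (edges, counts) with counts summing to the cluster count.
    """
    spans = np.asarray([c.span for c in clusters], dtype=float)
    if len(spans) == 0:
        return np.asarray([0.0, float(bin_width)]), np.zeros(1, dtype=int)
    n_bins = int(spans.max() // bin_width) + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(spans, bins=edges)
    return edges, counts.astype(int)
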