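"""Modified rainfall plots: inter-mutation distance vs chromosomal coordinate.

Unlike the classical rainfall plot (distance vs mutation index), the X axis
here is the genomic coordinate and the Y axis is log2 of the distance to the
previous SNV on the same chromosome, so clusters appear as low-lying runs at
their true genomic location.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import MaskSet, MutationClass, PooledVariantSet

#: log2 value at which zero distances (pooled duplicates) are drawn
LOG2_FLOOR = -1.0

#: horizontal guide lines (bp) in the rendered plot
GUIDE_LINES = (10, 100, 500, 1000)


@dataclass(frozen=True)
class RainfallPoint:
    chrom: str
    pos: int
    dist_prev: int
    log2_dist: float
    mclass: MutationClass


def rainfall_points(pooled: PooledVariantSet) -> list[RainfallPoint]:
    """One point per SNV except the first on each chromosome; dist_prev is
    the gap to the previous SNV in the pooled, position-sorted set. Zero
    distances (duplicate positions from different clones) are kept and
    rendered at the log2 floor."""
    points: list[RainfallPoint] = []
    for chrom, records in pooled.by_chromosome().items():
        for prev, cur in zip(records, records[1:]):
            d = cur.pos - prev.pos
            log2d = math.log2(d) if d > 0 else LOG2_FLOOR
            points.append(RainfallPoint(chrom, cur.pos, d, log2d, cur.mclass))
    return points


_CLASS_COLORS = {MutationClass.CT: "red", MutationClass.GA: "blue",
                 MutationClass.OTHER: "0.4"}


def render_rainfall(points: Sequence[RainfallPoint], out_path,
                    masks: Optional[MaskSet] = None,
                    gaps: Optional[MaskSet] = None,
                    highlights: Optional[Sequence[tuple[str, int, int]]] = None,
                    ) -> None:
    """Render per-chromosome rainfall panels to ``out_path`` (PNG/SVG).

    Masked regions are drawn as light grey vertical bands, assembly gaps as
    dark grey bands, and optional (chrom, start, end) highlights as zoomed
    sub-panels appended below the main grid.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({p.chrom for p in points})
    highlights = list(highlights or [])
    n_panels = max(1, len(chroms)) + len(highlights)
    fig, axes = plt.subplots(n_panels, 1, figsize=(10, 2.2 * n_panels),
                             squeeze=False)
    axes = axes.ravel()

    def _draw(ax, chrom, xlim=None):
        pts = [p for p in points if p.chrom == chrom]
        if xlim is not None:
            pts = [p for p in pts if xlim[0] <= p.pos <= xlim[1]]
        for mc, color in _CLASS_COLORS.items():
            xs = [p.pos for p in pts if p.mclass is mc]
            ys = [p.log2_dist for p in pts if p.mclass is mc]
            if xs:
                ax.scatter(xs, ys, s=6, c=color, label=mc.value, linewidths=0)
        for bands, color in ((masks, "0.85"), (gaps, "0.45")):
            if bands is not None:
                for start, end in bands.intervals(chrom):
                    ax.axvspan(start + 1, end, color=color, zorder=0)
        for d in GUIDE_LINES:
            ax.axhline(math.log2(d), lw=1.2,
                       color="magenta" if d == 500 else "0.2")
        if xlim is not None:
            ax.set_xlim(*xlim)
        ax.set_ylabel("log2 dist (bp)")
        ax.set_title(chrom, fontsize=9, loc="left")

    for ax, chrom in zip(axes, chroms or ["(empty)"]):
        if chrom == "(empty)":
            ax.set_title("no SNVs", fontsize=9)
        else:
            _draw(ax, chrom)
    for ax, (chrom, start, end) in zip(axes[max(1, len(chroms)):], highlights):
        _draw(ax, chrom, xlim=(start, end))
        ax.set_title(f"{chrom}:{start}-{end} (zoom)", fontsize=9, loc="left")
    axes[-1].set_xlabel("chromosomal coordinate (bp)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
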