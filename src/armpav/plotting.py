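"""Coverage-landscape plot: window medians, region, PAV calls, markers."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .armcheck import MarkerPlacement
from .coverage import HighCoverageRegion, WindowStat
from .pav import GeneCoverageStat, PRESENT


def plot_coverage_landscape(
    windows: Iterable[WindowStat],
    region: HighCoverageRegion | None = None,
    pav_stats: Iterable[GeneCoverageStat] = (),
    placements: Iterable[MarkerPlacement] = (),
    seq_id: str | None = None,
    out: str | Path | None = None,
):
    """Plot median depth per window along one sequence.

    The high-coverage region is shaded, gene calls drawn as green (present)
    and red (absent) ticks, marker placements as dashed vertical lines.
    Returns the matplotlib figure; saves to ``out`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    windows = list(windows)
    if seq_id is None:
        seq_id = region.seq_id if region is not None else windows[0].seq_id
    ws = [w for w in windows if w.seq_id == seq_id]

    fig, ax = plt.subplots(figsize=(10, 3.5))
    mids = [(w.start + w.end) / 2e6 for w in ws]
    ax.plot(mids, [w.median_depth for w in ws], color="tab:blue", lw=1.2,
            label="median depth / window")
    if region is not None and region.seq_id == seq_id:
        ax.axvspan(region.start / 1e6, region.end / 1e6, color="tab:blue",
                   alpha=0.08, label="high-coverage region")
    for s in pav_stats:
        if s.gene.seq_id != seq_id:
            continue
        color = "tab:green" if s.call == PRESENT else "tab:red"
        ax.plot([s.gene.start / 1e6, s.gene.end / 1e6], [-1.5, -1.5],
                color=color, lw=3, solid_capstyle="butt")
    for p in placements:
        if p.seq_id != seq_id:
            continue
        ax.axvline(p.pos / 1e6, ls="--", color="grey", lw=0.8)
        ax.annotate(p.arm_label, (p.pos / 1e6, ax.get_ylim()[1]),
                    fontsize=7, ha="center")
    ax.set_xlabel(f"{seq_id} position (Mb)")
    ax.set_ylabel("depth (X)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig
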