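"""Per-base depth, windowed median coverage and sorted-arm delineation.

Flow-sorted chromosome-arm reads pile up on the arm they came from and only
thinly elsewhere (contamination), so the arm shows up as a long contiguous
run of high-median 100-kb windows on one pseudomolecule.  This module
computes the depth track, the window medians and that run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .models import AlignmentRecord, DepthTrack

DEFAULT_WINDOW = 100_000
DEFAULT_MIN_MEDIAN = 5.0
DEFAULT_MAX_GAP_WINDOWS = 10


@dataclass(frozen=True)
class WindowStat:
    """Median depth over one window (0-based half-open, nominal 100 kb)."""

    seq_id: str
    start: int
    end: int
    median_depth: float


@dataclass(frozen=True)
class HighCoverageRegion:
    """Contiguous interval called as the sorted arm, with the rule parameters."""

    seq_id: str
    start: int
    end: int
    min_median: float
    max_gap_windows: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, seq_id: str, pos: int) -> bool:
        return seq_id == self.seq_id and self.start <= pos < self.end


def compute_depth(
    alignments: Iterable[AlignmentRecord],
    lengths: Mapping[str, int],
) -> DepthTrack:
    """Count, per base, the retained alignments covering it.

    Uses a difference-array accumulation: +1 at each interval start, -1 at
    each end, then a cumulative sum.  Total depth over all bases equals the
    summed reference-interval length of the input records (conservation).
    """
    diffs = {s: np.zeros(n + 1, dtype=np.int64) for s, n in lengths.items()}
    for rec in alignments:
        try:
            diff = diffs[rec.seq_id]
        except KeyError:
            raise ValueError(f"alignment on unknown sequence {rec.seq_id!r}") from None
        for s, e in rec.aligned_ref_intervals:
            if e > lengths[rec.seq_id]:
                raise ValueError(
                    f"alignment {rec.read_id} extends past end of {rec.seq_id}"
                )
            diff[s] += 1
            diff[e] -= 1
    return DepthTrack({s: np.cumsum(d[:-1]) for s, d in diffs.items()})


def windowed_median(
    track: DepthTrack, window: int = DEFAULT_WINDOW
) -> list[WindowStat]:
    """Tile each sequence into consecutive windows and take the depth median.

    The last window may be short and is included as-is.  The median is the
    standard middle-order statistic (mean of the two middle values for an
    even count).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    out: list[WindowStat] = []
    for seq_id, vec in track.items():
        for start in range(0, vec.size, window):
            end = min(start + window, vec.size)
            out.append(
                WindowStat(seq_id, start, end, float(np.median(vec[start:end])))
            )
    return out


def delineate_high_coverage_region(
    windows: list[WindowStat],
    min_median: float = DEFAULT_MIN_MEDIAN,
    max_gap_windows: int = DEFAULT_MAX_GAP_WINDOWS,
) -> HighCoverageRegion | None:
    """Find the longest run of high-median windows, tolerating short gaps.

    Windows with ``median_depth >= min_median`` are "high"; maximal runs of
    high windows separated by at most ``max_gap_windows`` consecutive low
    windows are merged.  The longest merged run wins (ties go leftmost); its
    boundaries are the first and last *high* window in the run, so gaps never
    extend the region outward.  Returns ``None`` when no window is high.
    """
    if not windows:
        return None
    seq_ids = {w.seq_id for w in windows}
    if len(seq_ids) != 1:
        raise ValueError("windows must come from a single sequence")
    ordered = sorted(windows, key=lambda w: w.start)
    high_idx = [i for i, w in enumerate(ordered) if w.median_depth >= min_median]
    if not high_idx:
        return None
    # Group high windows whose index gaps are small enough.
    runs: list[list[int]] = [[high_idx[0]]]
    for i in high_idx[1:]:
        if i - runs[-1][-1] - 1 <= max_gap_windows:
            runs[-1].append(i)
        else:
            runs.append([i])
    best = max(
        runs, key=lambda r: (ordered[r[-1]].end - ordered[r[0]].start, -r[0])
    )
    return HighCoverageRegion(
        seq_id=ordered[best[0]].seq_id,
        start=ordered[best[0]].start,
        end=ordered[best[-1]].end,
        min_median=min_median,
        max_gap_windows=max_gap_windows,
    )


def write_windows_tsv(windows: Iterable[WindowStat], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tmedian_depth\n")
        for w in windows:
            fh.write(f"{w.seq_id}\t{w.start}\t{w.end}\t{w.median_depth:g}\n")
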