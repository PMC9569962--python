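"""Core domain types for chromosome-arm presence/absence analysis.

All internal coordinates are 0-based half-open.  Conversion to and from the
1-based inclusive conventions of GFF3 and samtools-depth tables happens only
at the format boundary (:mod:`armpav.formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

Interval = tuple[int, int]


def _check_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    out = [(int(s), int(e)) for s, e in intervals]
    for s, e in out:
        if s >= e:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
    for (s0, e0), (s1, e1) in zip(out, out[1:]):
        if s1 < e0:
            raise ValueError("intervals must be sorted and disjoint")
    return out


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: span, CDS union of the primary transcript, flags.

    ``cds_intervals`` is the sorted, disjoint union of the CDS features of the
    primary (".1") transcript; empty when the gene model has no CDS, in which
    case downstream statistics fall back to the gene span.
    """

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "."
    cds_intervals: tuple[Interval, ...] = ()
    annotation_quality: str = "high"
    placed: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-.":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        ivals = _check_intervals(self.cds_intervals)
        for s, e in ivals:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: CDS outside gene span")
        object.__setattr__(self, "cds_intervals", tuple(ivals))

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def has_cds(self) -> bool:
        return bool(self.cds_intervals)

    def stat_intervals(self) -> tuple[Interval, ...]:
        """Intervals used for coverage statistics (CDS, or span fallback)."""
        if self.cds_intervals:
            return self.cds_intervals
        return ((self.start, self.end),)


@dataclass(frozen=True)
class AlignmentRecord:
    """A primary mapped alignment reduced to its reference-consuming intervals.

    Intervals follow pileup semantics: match/mismatch and deletion-in-read
    cigar operations consume reference and count as covered; insertions and
    clips do not; reference skips (``N``) split intervals.
    """

    read_id: str
    seq_id: str
    aligned_ref_intervals: tuple[Interval, ...]
    mapq: int
    is_primary_mapped: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"mapq {self.mapq} out of range")
        object.__setattr__(
            self, "aligned_ref_intervals",
            tuple(_check_intervals(self.aligned_ref_intervals)),
        )

    @property
    def reference_length(self) -> int:
        return sum(e - s for s, e in self.aligned_ref_intervals)


class DepthTrack:
    """Per-base sequencing depth for a set of reference sequences.

    A thin mapping ``seq_id -> np.ndarray`` of non-negative integer depths,
    one entry per base ("X" units).
    """

    def __init__(self, depths: Mapping[str, np.ndarray]):
        self._depths: dict[str, np.ndarray] = {}
        for seq_id, vec in depths.items():
            arr = np.asarray(vec)
            if arr.ndim != 1:
                raise ValueError(f"{seq_id}: depth vector must be 1-D")
            if arr.size and arr.min() < 0:
                raise ValueError(f"{seq_id}: negative depth")
            self._depths[seq_id] = arr.astype(np.int64, copy=False)

    @classmethod
    def zeros(cls, lengths: Mapping[str, int]) -> "DepthTrack":
        return cls({s: np.zeros(n, dtype=np.int64) for s, n in lengths.items()})

    def __getitem__(self, seq_id: str) -> np.ndarray:
        return self._depths[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._depths

    def __iter__(self):
        return iter(self._depths)

    def items(self):
        return self._depths.items()

    def lengths(self) -> dict[str, int]:
        return {s: int(v.size) for s, v in self._depths.items()}

    def total(self) -> int:
        """Sum of depth over all bases (equals total aligned reference bp)."""
        return int(sum(int(v.sum()) for v in self._depths.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthTrack):
            return NotImplemented
        if set(self._depths) != set(other._depths):
            return False
        return all(np.array_equal(v, other._depths[k]) for k, v in self._depths.items())

    def __repr__(self) -> str:
        return f"DepthTrack({self.lengths()})"


@dataclass(frozen=True)
class MarkerRecord:
    """An arm-diagnostic marker: a short sequence and/or a known placement."""

    marker_id: str
    arm_label: str
    sequence: str | None = None
    seq_id: str | None = None
    pos: int | None = None  # 0-based

    def __post_init__(self) -> None:
        if self.sequence is None and (self.seq_id is None or self.pos is None):
            raise ValueError(
                f"{self.marker_id}: need a sequence or a (seq_id, pos) placement"
            )


__all__ = [
    "Interval",
    "GeneModel",
    "AlignmentRecord",
    "DepthTrack",
    "MarkerRecord",
    "replace",
]
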