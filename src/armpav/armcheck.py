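"""Marker placement and chromosome-arm identity assignment.

Arm-diagnostic markers (e.g. PLUG intron-targeting markers) carried by one
arm only should co-locate with the high-coverage region if the sorted
material really is that arm.  Markers are placed by exact substring search on
both strands (short diagnostic sequences; an aligner would be overkill), or
passed through when placements are supplied pre-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import Seq

from .coverage import HighCoverageRegion
from .models import MarkerRecord

UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class MarkerPlacement:
    marker_id: str
    arm_label: str
    seq_id: str
    pos: int  # 0-based start of the match
    strand: str  # '+' or '-'
    in_region: bool | None = None


@dataclass(frozen=True)
class ArmAssignment:
    """Verdict on the sorted arm's identity, with per-label marker support."""

    verdict: str  # an arm label, or "undetermined"
    support: dict[str, tuple[int, int]]  # label -> (in_region, out_of_region)


def _find_all(haystack: str, needle: str, max_mismatches: int = 0) -> list[int]:
    if max_mismatches == 0:
        hits, start = [], haystack.find(needle)
        while start != -1:
            hits.append(start)
            start = haystack.find(needle, start + 1)
        return hits
    hits = []
    n, m = len(haystack), len(needle)
    for i in range(n - m + 1):
        mism = 0
        for a, b in zip(haystack[i:i + m], needle):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            hits.append(i)
    return hits


def locate_markers(
    markers: Iterable[MarkerRecord],
    reference: Mapping[str, str],
    max_mismatches: int = 0,
) -> tuple[list[MarkerPlacement], dict[str, str]]:
    """Place markers on the reference.

    Sequence markers are searched exactly (optionally allowing substitutions)
    on both strands of every sequence; a marker with zero hits is reported
    unplaced, one with several hits ambiguous.  Markers that already carry a
    position are passed through on the '+' strand.

    Returns the unique placements plus ``{marker_id: reason}`` for markers
    that could not be placed.
    """
    placements: list[MarkerPlacement] = []
    skipped: dict[str, str] = {}
    upper = {s: seq.upper() for s, seq in reference.items()}
    for m in markers:
        if m.sequence is None:
            placements.append(
                MarkerPlacement(m.marker_id, m.arm_label, m.seq_id, m.pos, "+")
            )
            continue
        fwd = m.sequence.upper()
        rev = str(Seq(fwd).reverse_complement())
        hits: list[tuple[str, int, str]] = []
        for seq_id, seq in upper.items():
            hits += [(seq_id, p, "+") for p in _find_all(seq, fwd, max_mismatches)]
            hits += [(seq_id, p, "-") for p in _find_all(seq, rev, max_mismatches)]
        if not hits:
            skipped[m.marker_id] = "unplaced"
        elif len(hits) > 1:
            skipped[m.marker_id] = f"ambiguous ({len(hits)} hits)"
        else:
            seq_id, pos, strand = hits[0]
            placements.append(
                MarkerPlacement(m.marker_id, m.arm_label, seq_id, pos, strand)
            )
    return placements, skipped


def assign_arm(
    placements: Iterable[MarkerPlacement],
    region: HighCoverageRegion | None,
    conflict_tolerance: int = 0,
) -> ArmAssignment:
    """Assign the sorted arm's identity from marker/region co-location.

    Per arm label, placements are counted inside vs outside the high-coverage
    region (placements on other sequences count as outside).  The verdict is
    the label with a strict majority of in-region markers, provided no other
    label has more than ``conflict_tolerance`` in-region markers; otherwise
    ``"undetermined"``.
    """
    support: dict[str, list[int]] = {}
    for p in placements:
        inside = region is not None and region.contains(p.seq_id, p.pos)
        counts = support.setdefault(p.arm_label, [0, 0])
        counts[0 if inside else 1] += 1
    frozen = {label: (c[0], c[1]) for label, c in sorted(support.items())}
    if not frozen or region is None:
        return ArmAssignment(UNDETERMINED, frozen)
    best = max(frozen, key=lambda lab: frozen[lab][0])
    best_in = frozen[best][0]
    if best_in == 0:
        return ArmAssignment(UNDETERMINED, frozen)
    for label, (inside, _) in frozen.items():
        if label == best:
            continue
        if inside >= best_in:  # tie or better: no strict majority
            return ArmAssignment(UNDETERMINED, frozen)
        if inside > conflict_tolerance:
            return ArmAssignment(UNDETERMINED, frozen)
    return ArmAssignment(best, frozen)


def annotate_in_region(
    placements: Iterable[MarkerPlacement], region: HighCoverageRegion | None
) -> list[MarkerPlacement]:
    """Return placements with ``in_region`` filled in against a region."""
    from dataclasses import replace

    return [
        replace(p, in_region=region is not None and region.contains(p.seq_id, p.pos))
        for p in placements
    ]


def write_placements_tsv(placements: Iterable[MarkerPlacement], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tarm_label\tseq_id\tpos\tstrand\tin_region\n")
        for p in placements:
            fh.write(
                f"{p.marker_id}\t{p.arm_label}\t{p.seq_id}\t{p.pos}\t{p.strand}\t"
                f"{'' if p.in_region is None else p.in_region}\n"
            )
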