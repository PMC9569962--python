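"""Readers and writers for the formats the pipeline touches.

External conventions: GFF3 and samtools-depth TSV are 1-based inclusive,
BED is 0-based half-open.  Everything internal is 0-based half-open; the
conversion happens here and only here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AlignmentRecord, DepthTrack, GeneModel, MarkerRecord

# Heuristic for assemblies where placement is encoded in the sequence name.
UNPLACED_SEQID_RE = re.compile(r"^(contig|scaffold|chrUn|un)", re.IGNORECASE)

#: GFF3 attribute key holding the annotation-quality flag, and its vocabulary.
#: The key varies between annotation releases; override per input.
DEFAULT_QUALITY_KEY = "annotation_quality"
DEFAULT_QUALITY = "high"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as ``{seq_id: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=seq_id, description="")
        for seq_id, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def fasta_lengths(path: str | Path) -> dict[str, int]:
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3 annotation

def _primary_transcript(db: gffutils.FeatureDB, gene) -> "gffutils.Feature | None":
    """The ".1" transcript of a gene, else the first mRNA by ID."""
    mrnas = sorted(db.children(gene, featuretype="mRNA"), key=lambda f: f.id)
    if not mrnas:
        return None
    for m in mrnas:
        if m.id.endswith(".1"):
            return m
    return mrnas[0]


def read_annotation(
    path: str | Path,
    quality_key: str = DEFAULT_QUALITY_KEY,
    default_quality: str = DEFAULT_QUALITY,
    placed_seq_ids: set[str] | None = None,
) -> list[GeneModel]:
    """Parse a GFF3 file into :class:`GeneModel` objects.

    Per gene, the CDS union of the primary (".1") transcript is taken; other
    isoforms are ignored.  1-based inclusive GFF3 coordinates are converted to
    0-based half-open.  A gene lacking CDS is retained with empty
    ``cds_intervals`` (downstream code flags it as span-fallback).

    Parameters
    ----------
    quality_key:
        GFF3 attribute on the gene feature holding the high/low annotation
        quality flag; genes without it get ``default_quality``.
    placed_seq_ids:
        Sequence names considered pseudomolecules.  When ``None``, placement
        is inferred from the sequence name (contig/scaffold/chrUn prefixes
        are treated as unplaced).
    """
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # gffutils reports the offending line
        raise ValueError(f"malformed GFF3 {path}: {exc}") from exc

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrna = _primary_transcript(db, gene)
        cds: list[tuple[int, int]] = []
        if mrna is not None:
            for c in db.children(mrna, featuretype="CDS", order_by="start"):
                cds.append((c.start - 1, c.end))
        cds = _merge_intervals(cds)
        quality = gene.attributes.get(quality_key, [default_quality])[0]
        if placed_seq_ids is not None:
            placed = gene.seqid in placed_seq_ids
        else:
            placed = not UNPLACED_SEQID_RE.match(gene.seqid)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else ".",
                cds_intervals=tuple(cds),
                annotation_quality=quality,
                placed=placed,
            )
        )
    return genes


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def write_annotation(
    genes: Iterable[GeneModel],
    path: str | Path,
    quality_key: str = DEFAULT_QUALITY_KEY,
) -> None:
    """Write gene models as GFF3 (gene + one mRNA + CDS features).

    Internal 0-based half-open coordinates go back to 1-based inclusive, so
    a read/write round trip is exact.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            strand = g.strand if g.strand in "+-" else "."
            attrs = f"ID={g.gene_id};{quality_key}={g.annotation_quality}"
            fh.write(
                f"{g.seq_id}\tarmpav\tgene\t{g.start + 1}\t{g.end}\t.\t{strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                f"{g.seq_id}\tarmpav\tmRNA\t{g.start + 1}\t{g.end}\t.\t{strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds_intervals, 1):
                fh.write(
                    f"{g.seq_id}\tarmpav\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# SAM/BAM alignments

def read_alignments(
    path: str | Path,
    min_mapq: int = 30,
    reference_lengths: Mapping[str, int] | None = None,
) -> Iterator[AlignmentRecord]:
    """Stream primary mapped alignments with MAPQ >= ``min_mapq``.

    Unmapped, secondary and supplementary records are excluded.  Each record
    is reduced to its reference-consuming intervals: M/=/X and D cigar
    operations cover reference bases, N splits the interval, I/S/H/P are
    ignored — i.e. pileup semantics.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        if reference_lengths is not None:
            for name in af.references:
                if name not in reference_lengths:
                    raise ValueError(
                        f"alignment header sequence {name!r} missing from reference"
                    )
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            yield AlignmentRecord(
                read_id=rec.query_name,
                seq_id=rec.reference_name,
                aligned_ref_intervals=tuple(_cigar_ref_intervals(rec)),
                mapq=rec.mapping_quality,
            )


_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X
_REF_SKIP = 3  # N


def _cigar_ref_intervals(rec: "pysam.AlignedSegment") -> list[tuple[int, int]]:
    pos = rec.reference_start
    intervals: list[tuple[int, int]] = []
    cur_start = None
    for op, length in rec.cigartuples or ():
        if op in _REF_CONSUMING:
            if cur_start is None:
                cur_start = pos
            pos += length
        elif op == _REF_SKIP:
            if cur_start is not None:
                intervals.append((cur_start, pos))
                cur_start = None
            pos += length
        # I, S, H, P: consume no reference
    if cur_start is not None:
        intervals.append((cur_start, pos))
    return intervals


# ---------------------------------------------------------------------------
# samtools-depth style TSV

def read_depth_table(
    path: str | Path, lengths: Mapping[str, int]
) -> DepthTrack:
    """Read a depth TSV (seq_id, 1-based pos, depth) into a DepthTrack.

    Positions with zero depth may be omitted in the file and are
    reconstructed from ``lengths``.  Positions must be strictly increasing
    within each sequence.
    """
    track = DepthTrack.zeros(lengths)
    df = pd.read_csv(
        str(path), sep="\t", header=None, names=["seq_id", "pos", "depth"],
        dtype={"seq_id": str, "pos": np.int64, "depth": np.int64},
        comment="#",
    )
    if df.empty:
        return track
    for seq_id, sub in df.groupby("seq_id", sort=False):
        if seq_id not in track:
            raise ValueError(f"depth table names unknown sequence {seq_id!r}")
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"non-monotone positions for {seq_id!r}")
        if pos[0] < 1 or pos[-1] > lengths[seq_id]:
            raise ValueError(f"position out of range for {seq_id!r}")
        track[seq_id][pos - 1] = sub["depth"].to_numpy()
    return track


def write_depth_table(
    track: DepthTrack, path: str | Path, include_zeros: bool = False
) -> None:
    """Write a DepthTrack as a samtools-depth style TSV (1-based positions)."""
    with open(path, "w") as fh:
        for seq_id, vec in track.items():
            if include_zeros:
                pos = np.arange(1, vec.size + 1)
                depths = vec
            else:
                (idx,) = np.nonzero(vec)
                pos = idx + 1
                depths = vec[idx]
            for p, d in zip(pos.tolist(), depths.tolist()):
                fh.write(f"{seq_id}\t{p}\t{d}\n")


# ---------------------------------------------------------------------------
# BED

def write_bed(
    intervals: Iterable[tuple[str, int, int] | tuple[str, int, int, str]],
    path: str | Path,
) -> None:
    """Write (seq_id, start, end[, name]) intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str | None]]:
    out: list[tuple[str, int, int, str | None]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[3] if len(parts) > 3 else None
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


# ---------------------------------------------------------------------------
# Marker TSV

_MARKER_COLUMNS = ["marker_id", "arm_label", "sequence", "seq_id", "pos_1based"]


def read_markers(path: str | Path) -> list[MarkerRecord]:
    """Read a marker TSV (marker_id, arm_label, sequence, seq_id, pos_1based).

    ``sequence`` or the (seq_id, pos_1based) pair may be empty, not both.
    """
    df = pd.read_csv(str(path), sep="\t", dtype=str).fillna("")
    missing = [c for c in _MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marker table missing columns {missing}")
    markers = []
    for row in df.itertuples(index=False):
        seq = row.sequence or None
        seq_id = row.seq_id or None
        pos = int(row.pos_1based) - 1 if row.pos_1based else None
        markers.append(
            MarkerRecord(row.marker_id, row.arm_label, sequence=seq,
                         seq_id=seq_id, pos=pos)
        )
    return markers


def write_markers(markers: Iterable[MarkerRecord], path: str | Path) -> None:
    rows = [
        {
            "marker_id": m.marker_id,
            "arm_label": m.arm_label,
            "sequence": m.sequence or "",
            "seq_id": m.seq_id or "",
            "pos_1based": "" if m.pos is None else m.pos + 1,
        }
        for m in markers
    ]
    pd.DataFrame(rows, columns=_MARKER_COLUMNS).to_csv(str(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-gene PAV report

PAV_REPORT_COLUMNS = [
    "gene_id", "seq_id", "start", "end", "quality", "placed", "cds_length",
    "bases_at_or_above", "horizontal_coverage", "median_depth", "call",
    "regime", "span_fallback",
]


def write_pav_report(stats: Iterable, path: str | Path) -> None:
    """Write GeneCoverageStat rows as TSV, one row per gene."""
    rows = [s.to_row() for s in stats]
    pd.DataFrame(rows, columns=PAV_REPORT_COLUMNS).to_csv(
        str(path), sep="\t", index=False, float_format="%.6g"
    )


def read_pav_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")
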