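"""Synthetic flow-sorted chromosome-arm datasets with complete ground truth.

The generator emulates the inputs of an isolated-arm sequencing study:

* one long pseudomolecule whose proximal half is the sorted arm (a
  telocentric short arm) and whose distal half is the unsequenced long arm;
* a larger host-genome background (wheat-like sequences) that contaminant
  reads are drawn from — flow sorting is imperfect, so only ``purity`` of
  the reads originate from the arm (default 0.87);
* unplaced contigs, some of which truly belong to the arm and therefore
  receive arm-level depth;
* per-locus log-normal amplification factors emulating the strong
  locus-to-locus depth bias of multiple displacement amplification (MDA);
* known deleted gene blocks: arm-origin reads never touch a deleted gene,
  so downstream absence calls are forced and exactly recoverable;
* arm-diagnostic markers planted uniquely, some reverse-complemented.

Reads are emitted as FASTQ and as *perfect* ungapped SAM alignments at their
true origins (MAPQ 60), standing in for an external aligner so the full
pipeline runs without one.  Every output is a pure function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .formats import write_annotation, write_fasta, write_markers
from .models import GeneModel, MarkerRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_a] = _b


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study; defaults are the study template.

    The default template mirrors the real study's structure at desk scale:
    200 arm genes (scaled down from ~3,500), one block of 7 consecutive
    deleted genes, one 81-gene window with 65 deletions, purity 0.87, 30X
    mean arm depth with log-normal MDA bias, 150 bp paired-end reads, four
    in-arm "7RS" markers and two off-arm "7RL" markers.
    """

    seed: int = 0
    # genome layout (bp)
    arm_len: int = 1_000_000
    offarm_len: int = 1_000_000
    other_seq_lens: tuple[int, ...] = (750_000, 750_000)
    unplaced_lens: tuple[int, ...] = (20_000,) * 6
    n_unplaced_arm: int = 3  # the first n unplaced contigs belong to the arm
    pseudomolecule_id: str = "chr7R"
    # genes
    n_genes_arm: int = 200
    genes_per_unplaced: int = 1
    gene_len_range: tuple[int, int] = (600, 1200)
    cds_fraction: float = 0.7
    high_quality_fraction: float = 0.7
    # deletions (arm gene indices, 0-based along the arm)
    deleted_blocks: tuple[tuple[int, int], ...] = ((60, 7),)
    interspersed_start: int = 100
    interspersed_template: tuple[int, int] | None = (81, 65)  # (window, absent)
    # reads
    purity: float = 0.87
    mean_depth: float = 30.0
    mda_sigma: float = 0.5
    mda_locus: int = 5_000
    read_len: int = 150
    paired: bool = True
    insert: int = 400
    error_rate: float = 0.0
    # markers
    arm_marker_label: str = "7RS"
    off_marker_label: str = "7RL"
    n_arm_markers: int = 4
    n_off_markers: int = 2
    marker_len: int = 40

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        if self.n_unplaced_arm > len(self.unplaced_lens):
            raise ValueError("n_unplaced_arm exceeds number of unplaced contigs")
        idx = set()
        for start, n in self.deleted_blocks:
            block = range(start, start + n)
            if start < 0 or start + n > self.n_genes_arm:
                raise ValueError("deleted block outside arm gene range")
            if idx & set(block):
                raise ValueError("deleted blocks overlap")
            idx |= set(block)
        if self.interspersed_template is not None:
            window, absent = self.interspersed_template
            if absent > window:
                raise ValueError("interspersed template: absent > window")
            span = set(range(self.interspersed_start, self.interspersed_start + window))
            if self.interspersed_start + window > self.n_genes_arm:
                raise ValueError("interspersed template outside arm gene range")
            if idx & span:
                raise ValueError("interspersed template overlaps a deleted block")

    @property
    def frag_len(self) -> int:
        return self.insert if self.paired else self.read_len


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset."""

    deleted_gene_ids: frozenset[str]
    arm_unplaced_gene_ids: frozenset[str]
    marker_truth: dict[str, tuple[str, int, str]]  # id -> (seq_id, pos, strand)
    arm_region: tuple[str, int, int]  # the true sorted-arm interval
    # filled by simulate_reads:
    read_is_arm: np.ndarray | None = None

    def to_json(self) -> dict:
        d = {
            "deleted_gene_ids": sorted(self.deleted_gene_ids),
            "arm_unplaced_gene_ids": sorted(self.arm_unplaced_gene_ids),
            "marker_truth": {k: list(v) for k, v in sorted(self.marker_truth.items())},
            "arm_region": list(self.arm_region),
        }
        if self.read_is_arm is not None:
            d["n_reads_arm"] = int(self.read_is_arm.sum())
            d["n_reads_total"] = int(self.read_is_arm.size)
        return d


@dataclass
class SimulatedReference:
    config: SimConfig
    sequences: dict[str, str]
    genes: list[GeneModel]
    markers: list[MarkerRecord]
    truth: TruthTable

    def lengths(self) -> dict[str, int]:
        return {s: len(seq) for s, seq in self.sequences.items()}


@dataclass
class ReadSet:
    """Simulated fragments; each yields one read (single-end) or a pair."""

    config: SimConfig
    seq_ids: list[str]  # per-fragment target sequence
    starts: np.ndarray  # per-fragment 0-based start
    is_arm: np.ndarray  # per-fragment origin flag
    r1: list[str]  # reference-forward sequence of read 1
    r2: list[str] | None  # reference-forward sequence of read 2 (paired only)

    @property
    def n_fragments(self) -> int:
        return len(self.seq_ids)

    @property
    def n_reads(self) -> int:
        return self.n_fragments * (2 if self.config.paired else 1)


# ---------------------------------------------------------------------------
# reference simulation

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _make_cds(rng: np.random.Generator, start: int, end: int,
              cds_fraction: float) -> tuple[tuple[int, int], ...]:
    """Split a gene span into 1-4 CDS intervals totalling ~cds_fraction."""
    length = end - start
    total_cds = max(1, int(round(length * cds_fraction)))
    k = int(rng.integers(1, 5))
    k = min(k, max(1, total_cds // 30))
    exon = np.full(k, total_cds // k)
    exon[: total_cds % k] += 1
    slack = length - total_cds
    # distribute the non-CDS slack into k+1 gaps (ends may be UTR-like)
    cuts = np.sort(rng.integers(0, slack + 1, size=k)) if slack else np.zeros(k, int)
    gaps = np.diff(np.concatenate([[0], cuts]))
    intervals = []
    pos = start
    for g, e in zip(gaps, exon):
        pos += int(g)
        intervals.append((pos, pos + int(e)))
        pos += int(e)
    return tuple(intervals)


def _interspersed_absent_locals(window: int, n_absent: int) -> set[int]:
    """Local indices (0..window-1) of absent genes in the interspersed block.

    The present genes are spread evenly through the interior so that the
    block starts and ends on absent genes and present runs never exceed one.
    """
    n_present = window - n_absent
    present = {int(round((i + 1) * window / (n_present + 1))) for i in range(n_present)}
    if len(present) != n_present or 0 in present or window - 1 in present:
        raise ValueError("cannot place interspersed present genes for this template")
    return set(range(window)) - present


def deleted_arm_indices(config: SimConfig) -> set[int]:
    """Arm gene indices deleted from the sorted arm under this config."""
    idx: set[int] = set()
    for start, n in config.deleted_blocks:
        idx |= set(range(start, start + n))
    if config.interspersed_template is not None:
        window, absent = config.interspersed_template
        locals_ = _interspersed_absent_locals(window, absent)
        idx |= {config.interspersed_start + i for i in locals_}
    return idx


def simulate_reference(config: SimConfig) -> SimulatedReference:
    """Build the reference FASTA, gene annotation, markers and gene truth."""
    rng = np.random.default_rng([config.seed, 0])
    chrom = config.pseudomolecule_id
    seq_arrays: dict[str, np.ndarray] = {
        chrom: _random_seq(rng, config.arm_len + config.offarm_len)
    }
    for i, n in enumerate(config.other_seq_lens, 1):
        seq_arrays[f"chrW{i}"] = _random_seq(rng, n)
    unplaced_ids = []
    for i, n in enumerate(config.unplaced_lens, 1):
        name = f"contig_{i}"
        unplaced_ids.append(name)
        seq_arrays[name] = _random_seq(rng, n)

    # --- arm genes: one per equal slot, jittered, hence non-overlapping
    slot = config.arm_len // config.n_genes_arm
    lo, hi = config.gene_len_range
    if slot < hi + 2:
        raise ValueError(
            f"cannot pack {config.n_genes_arm} genes of up to {hi} bp "
            f"into a {config.arm_len} bp arm"
        )
    genes: list[GeneModel] = []
    for i in range(config.n_genes_arm):
        glen = int(rng.integers(lo, hi + 1))
        start = slot * i + int(rng.integers(0, slot - glen))
        end = start + glen
        genes.append(
            GeneModel(
                gene_id=f"gene{i:04d}",
                seq_id=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                cds_intervals=_make_cds(rng, start, end, config.cds_fraction),
                annotation_quality=(
                    "high" if rng.random() < config.high_quality_fraction else "low"
                ),
                placed=True,
            )
        )

    # --- unplaced-contig genes
    arm_unplaced_gene_ids: set[str] = set()
    for j, name in enumerate(unplaced_ids):
        clen = len(seq_arrays[name])
        uslot = clen // config.genes_per_unplaced
        for k in range(config.genes_per_unplaced):
            glen = int(rng.integers(lo, min(hi, uslot - 2) + 1))
            start = uslot * k + int(rng.integers(0, uslot - glen))
            gid = f"{name}_gene{k}"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    seq_id=name,
                    start=start,
                    end=start + glen,
                    strand="+" if rng.random() < 0.5 else "-",
                    cds_intervals=_make_cds(rng, start, start + glen,
                                            config.cds_fraction),
                    annotation_quality=(
                        "high" if rng.random() < config.high_quality_fraction
                        else "low"
                    ),
                    placed=False,
                )
            )
            if j < config.n_unplaced_arm:
                arm_unplaced_gene_ids.add(gid)

    deleted_ids = frozenset(
        f"gene{i:04d}" for i in deleted_arm_indices(config)
    )

    # --- markers: unique random k-mers overwritten into the reference
    markers: list[MarkerRecord] = []
    marker_truth: dict[str, tuple[str, int, str]] = {}
    specs = []
    for i in range(config.n_arm_markers):
        frac = (i + 0.5) / config.n_arm_markers
        pos = int(frac * (config.arm_len - config.marker_len))
        specs.append((f"{config.arm_marker_label}_m{i + 1}", config.arm_marker_label,
                      pos, "+" if i % 2 == 0 else "-"))
    for i in range(config.n_off_markers):
        frac = (i + 0.5) / config.n_off_markers
        pos = config.arm_len + int(frac * (config.offarm_len - config.marker_len))
        specs.append((f"{config.off_marker_label}_m{i + 1}", config.off_marker_label,
                      pos, "+" if i % 2 == 0 else "-"))
    chrom_arr = seq_arrays[chrom]
    for marker_id, label, pos, strand in specs:
        mseq = _random_seq(rng, config.marker_len)
        planted = mseq if strand == "+" else _COMPLEMENT[mseq][::-1]
        chrom_arr[pos : pos + config.marker_len] = planted
        markers.append(
            MarkerRecord(marker_id, label, sequence=mseq.tobytes().decode())
        )
        marker_truth[marker_id] = (chrom, pos, strand)

    sequences = {s: a.tobytes().decode() for s, a in seq_arrays.items()}
    _assert_markers_unique(markers, sequences)

    truth = TruthTable(
        deleted_gene_ids=deleted_ids,
        arm_unplaced_gene_ids=frozenset(arm_unplaced_gene_ids),
        marker_truth=marker_truth,
        arm_region=(chrom, 0, config.arm_len),
    )
    genes.sort(key=lambda g: (g.seq_id, g.start))
    return SimulatedReference(config, sequences, genes, markers, truth)


def _assert_markers_unique(markers, sequences) -> None:
    from .armcheck import _find_all
    from Bio.Seq import Seq

    for m in markers:
        rc = str(Seq(m.sequence).reverse_complement())
        hits = sum(
            len(_find_all(s, m.sequence)) + len(_find_all(s, rc))
            for s in sequences.values()
        )
        if hits != 1:
            raise RuntimeError(f"marker {m.marker_id} not unique ({hits} hits)")


# ---------------------------------------------------------------------------
# read simulation

def _allowed_start_segments(
    seq_len: int, frag_len: int, forbidden: list[tuple[int, int]],
    limit: tuple[int, int] | None = None,
) -> list[tuple[int, int]]:
    """Start-position ranges whose fragment avoids every forbidden interval."""
    lo, hi = (0, seq_len) if limit is None else limit
    hi = hi - frag_len + 1
    segments = []
    pos = lo
    for s, e in sorted(forbidden):
        seg_end = min(s - frag_len + 1, hi)
        if seg_end > pos:
            segments.append((pos, seg_end))
        pos = max(pos, e)
    if hi > pos:
        segments.append((pos, hi))
    return segments


def simulate_reads(
    config: SimConfig, reference: SimulatedReference
) -> ReadSet:
    """Sample fragments with flow-sort impurity and MDA amplification bias.

    Each fragment is arm-origin with probability ``purity``; arm fragments
    are placed on the arm (plus arm-member unplaced contigs) with start
    probabilities proportional to per-locus log-normal amplification
    factors, never overlapping a deleted gene.  Contaminant fragments fall
    uniformly on the off-arm remainder, the background sequences and the
    non-arm unplaced contigs.  Expected depth over non-deleted arm bases
    equals ``mean_depth``.
    """
    rng = np.random.default_rng([config.seed, 1])
    chrom = config.pseudomolecule_id
    frag_len = config.frag_len
    L = config.read_len
    genes_by_seq: dict[str, list[tuple[int, int]]] = {}
    deleted = reference.truth.deleted_gene_ids
    for g in reference.genes:
        if g.gene_id in deleted:
            genes_by_seq.setdefault(g.seq_id, []).append((g.start, g.end))

    unplaced_ids = [f"contig_{i + 1}" for i in range(len(config.unplaced_lens))]
    arm_pool = [(chrom, (0, config.arm_len))] + [
        (u, None) for u in unplaced_ids[: config.n_unplaced_arm]
    ]
    contam_pool = [(chrom, (config.arm_len, config.arm_len + config.offarm_len))] + [
        (f"chrW{i + 1}", None) for i in range(len(config.other_seq_lens))
    ] + [(u, None) for u in unplaced_ids[config.n_unplaced_arm :]]

    # --- arm sampling distribution: 5-kb loci weighted by log-normal factors
    chunk_seq: list[str] = []
    chunk_lo: list[int] = []
    chunk_hi: list[int] = []
    chunk_w: list[float] = []
    covered_len = 0  # non-deleted bases of the arm pool
    for seq_id, limit in arm_pool:
        seq_len = len(reference.sequences[seq_id])
        forb = genes_by_seq.get(seq_id, [])
        segs = _allowed_start_segments(seq_len, frag_len, forb, limit)
        if not segs:
            continue
        span = (limit or (0, seq_len))
        covered_len += (span[1] - span[0]) - sum(e - s for s, e in forb)
        n_loci = -(-seq_len // config.mda_locus)
        factors = rng.lognormal(mean=0.0, sigma=config.mda_sigma, size=n_loci)
        for s, e in segs:
            b = s
            while b < e:
                nb = min(e, (b // config.mda_locus + 1) * config.mda_locus)
                chunk_seq.append(seq_id)
                chunk_lo.append(b)
                chunk_hi.append(nb)
                chunk_w.append((nb - b) * factors[b // config.mda_locus])
                b = nb
    if covered_len <= 0:
        raise ValueError("deleted intervals cover the whole arm")

    reads_per_frag = 2 if config.paired else 1
    n_arm_target = config.mean_depth * covered_len / (reads_per_frag * L)
    n_frags = int(round(n_arm_target / config.purity))
    is_arm = rng.random(n_frags) < config.purity
    n_arm = int(is_arm.sum())
    n_con = n_frags - n_arm

    # arm fragment positions
    w = np.asarray(chunk_w)
    chunk_idx = rng.choice(len(w), size=n_arm, p=w / w.sum())
    lo_arr = np.asarray(chunk_lo)
    hi_arr = np.asarray(chunk_hi)
    arm_starts = lo_arr[chunk_idx] + (
        rng.random(n_arm) * (hi_arr[chunk_idx] - lo_arr[chunk_idx])
    ).astype(np.int64)
    arm_seqs = [chunk_seq[i] for i in chunk_idx]

    # contaminant fragment positions: uniform over the pool
    con_ranges = []
    for seq_id, limit in contam_pool:
        seq_len = len(reference.sequences[seq_id])
        lo, hi = (0, seq_len) if limit is None else limit
        hi = hi - frag_len + 1
        if hi > lo:
            con_ranges.append((seq_id, lo, hi))
    con_lens = np.array([hi - lo for _, lo, hi in con_ranges], dtype=float)
    con_pick = rng.choice(len(con_ranges), size=n_con, p=con_lens / con_lens.sum())
    con_starts = np.array(
        [con_ranges[i][1] for i in con_pick], dtype=np.int64
    ) + (rng.random(n_con) * con_lens[con_pick]).astype(np.int64)
    con_seqs = [con_ranges[i][0] for i in con_pick]

    # interleave back into fragment order
    seq_ids = [""] * n_frags
    starts = np.zeros(n_frags, dtype=np.int64)
    ai = ci = 0
    for i in range(n_frags):
        if is_arm[i]:
            seq_ids[i], starts[i] = arm_seqs[ai], arm_starts[ai]
            ai += 1
        else:
            seq_ids[i], starts[i] = con_seqs[ci], con_starts[ci]
            ci += 1

    # read sequences (reference-forward orientation)
    byte_seqs = {s: np.frombuffer(seq.encode(), dtype=np.uint8)
                 for s, seq in reference.sequences.items()}

    def slice_read(seq_id: str, start: int) -> np.ndarray:
        return byte_seqs[seq_id][start : start + L].copy()

    r1_arr = [slice_read(s, p) for s, p in zip(seq_ids, starts.tolist())]
    r2_arr = None
    if config.paired:
        r2_arr = [
            slice_read(s, p + frag_len - L) for s, p in zip(seq_ids, starts.tolist())
        ]
    if config.error_rate > 0:
        _apply_errors(rng, r1_arr, config.error_rate)
        if r2_arr is not None:
            _apply_errors(rng, r2_arr, config.error_rate)

    reference.truth.read_is_arm = np.repeat(is_arm, reads_per_frag)
    return ReadSet(
        config=config,
        seq_ids=seq_ids,
        starts=starts,
        is_arm=is_arm,
        r1=[a.tobytes().decode() for a in r1_arr],
        r2=None if r2_arr is None else [a.tobytes().decode() for a in r2_arr],
    )


def _apply_errors(rng: np.random.Generator, reads: list[np.ndarray],
                  rate: float) -> None:
    for arr in reads:
        n_err = rng.binomial(arr.size, rate)
        if not n_err:
            continue
        pos = rng.choice(arr.size, size=n_err, replace=False)
        for p in pos:
            choices = _BASES[_BASES != arr[p]]
            arr[p] = rng.choice(choices)


# ---------------------------------------------------------------------------
# emitters

def _revcomp(seq: str) -> str:
    return _COMPLEMENT[np.frombuffer(seq.encode(), dtype=np.uint8)][::-1].tobytes().decode()


def emit_perfect_alignments(
    reads: ReadSet, lengths: dict[str, int], path: str | Path
) -> None:
    """Write every read as a primary, ungapped SAM alignment at its origin.

    Stands in for an external aligner: CIGAR is all-match, MAPQ 60, pairs are
    flagged properly paired with read 2 on the reverse strand.
    """
    cfg = reads.config
    L = cfg.read_len
    qual = "I" * L
    cigar = f"{L}M"
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for seq_id, n in lengths.items():
            fh.write(f"@SQ\tSN:{seq_id}\tLN:{n}\n")
        fh.write("@PG\tID:armpav-sim\tPN:armpav-sim\n")
        for i in range(reads.n_fragments):
            name = f"sim{i:07d}_{'arm' if reads.is_arm[i] else 'con'}"
            seq_id = reads.seq_ids[i]
            p1 = int(reads.starts[i])
            if cfg.paired:
                p2 = p1 + cfg.frag_len - L
                tlen = cfg.frag_len
                fh.write(
                    f"{name}\t99\t{seq_id}\t{p1 + 1}\t60\t{cigar}\t=\t{p2 + 1}\t"
                    f"{tlen}\t{reads.r1[i]}\t{qual}\n"
                    f"{name}\t147\t{seq_id}\t{p2 + 1}\t60\t{cigar}\t=\t{p1 + 1}\t"
                    f"{-tlen}\t{reads.r2[i]}\t{qual}\n"
                )
            else:
                fh.write(
                    f"{name}\t0\t{seq_id}\t{p1 + 1}\t60\t{cigar}\t*\t0\t0\t"
                    f"{reads.r1[i]}\t{qual}\n"
                )


def write_fastq(reads: ReadSet, path_r1: str | Path,
                path_r2: str | Path | None = None) -> None:
    """Write reads as FASTQ; read 2 is reverse-complemented to read orientation."""
    cfg = reads.config
    qual = "I" * cfg.read_len
    if cfg.paired and path_r2 is None:
        raise ValueError("paired reads need a second FASTQ path")
    with open(path_r1, "w") as fh:
        for i, seq in enumerate(reads.r1):
            name = f"sim{i:07d}_{'arm' if reads.is_arm[i] else 'con'}"
            fh.write(f"@{name}/1\n{seq}\n+\n{qual}\n")
    if cfg.paired:
        with open(path_r2, "w") as fh:
            for i, seq in enumerate(reads.r2):
                name = f"sim{i:07d}_{'arm' if reads.is_arm[i] else 'con'}"
                fh.write(f"@{name}/2\n{_revcomp(seq)}\n+\n{qual}\n")


def write_dataset(
    config: SimConfig, outdir: str | Path, fastq: bool = False
) -> dict[str, Path]:
    """Simulate and write a full dataset; returns the paths written.

    Emits reference FASTA, gene annotation GFF3, marker TSV, perfect
    alignments SAM, the truth JSON, and (optionally) paired FASTQ.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = simulate_reference(config)
    reads = simulate_reads(config, ref)
    paths = {
        "reference": outdir / "reference.fa",
        "annotation": outdir / "annotation.gff3",
        "markers": outdir / "markers.tsv",
        "alignments": outdir / "alignments.sam",
        "truth": outdir / "truth.json",
    }
    write_fasta(ref.sequences, paths["reference"])
    write_annotation(ref.genes, paths["annotation"])
    write_markers(ref.markers, paths["markers"])
    emit_perfect_alignments(reads, ref.lengths(), paths["alignments"])
    if fastq:
        paths["fastq_r1"] = outdir / "reads_R1.fastq"
        if config.paired:
            paths["fastq_r2"] = outdir / "reads_R2.fastq"
        write_fastq(reads, paths["fastq_r1"], paths.get("fastq_r2"))
    with open(paths["truth"], "w") as fh:
        json.dump(ref.truth.to_json(), fh, indent=1, sort_keys=True)
    return paths
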