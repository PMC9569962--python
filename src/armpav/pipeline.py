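"""End-to-end orchestration: depth -> windows -> region -> PAV -> clusters
-> unplaced rescue -> marker arm check, with a consolidated report.

Stages run in a fixed order; every artifact is written to the output
directory and every parameter and count is logged, so a run is
self-describing.  A failing stage aborts with the stage named; artifacts
written so far are retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

from . import armcheck, clusters as clusters_mod, coverage, formats, pav
from .coverage import HighCoverageRegion
from .models import DepthTrack, GeneModel

logger = logging.getLogger("armpav")


@dataclass
class RunConfig:
    """Paths and thresholds for a pipeline run.

    Exactly one of ``alignments`` (SAM/BAM) or ``depth_table``
    (samtools-depth TSV) must be supplied.  ``target_seq`` selects the
    pseudomolecule to delineate; by default the longest reference sequence.
    """

    reference: Path
    annotation: Path
    outdir: Path
    alignments: Path | None = None
    depth_table: Path | None = None
    markers: Path | None = None
    target_seq: str | None = None
    min_mapq: int = 30
    window: int = coverage.DEFAULT_WINDOW
    min_median: float = coverage.DEFAULT_MIN_MEDIAN
    max_gap_windows: int = coverage.DEFAULT_MAX_GAP_WINDOWS
    default_thresholds: pav.PAVThresholds = field(
        default_factory=lambda: pav.DEFAULT_THRESHOLDS
    )
    conservative_thresholds: pav.PAVThresholds = field(
        default_factory=lambda: pav.CONSERVATIVE_THRESHOLDS
    )
    cluster_max_gap: int = clusters_mod.DEFAULT_MAX_GAP
    cluster_min_size: int = clusters_mod.DEFAULT_MIN_CLUSTER_SIZE
    containment: bool = False  # True: gene must lie fully inside the region
    quality_key: str = formats.DEFAULT_QUALITY_KEY
    skip_clusters: bool = False
    skip_rescue: bool = False
    skip_markers: bool = False

    def __post_init__(self) -> None:
        if (self.alignments is None) == (self.depth_table is None):
            raise ValueError("supply exactly one of alignments/depth_table")

    def params_dict(self) -> dict:
        d = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(self).items()
        }
        d["default_thresholds"] = asdict(self.default_thresholds)
        d["conservative_thresholds"] = asdict(self.conservative_thresholds)
        return d


@dataclass
class RunReport:
    """Consolidated results of one pipeline run."""

    region: HighCoverageRegion | None
    pav_stats: list[pav.GeneCoverageStat]
    clusters: list[clusters_mod.AbsentCluster]
    rescued: list[pav.GeneCoverageStat]
    arm_assignment: armcheck.ArmAssignment | None
    marker_placements: list[armcheck.MarkerPlacement]
    unplaced_markers: dict[str, str]
    params: dict

    @property
    def n_genes_in_region(self) -> int:
        return len(self.pav_stats)

    @property
    def n_present(self) -> int:
        return sum(1 for s in self.pav_stats if s.call == pav.PRESENT)

    @property
    def n_absent(self) -> int:
        return sum(1 for s in self.pav_stats if s.call == pav.ABSENT)

    @property
    def n_span_fallback(self) -> int:
        return sum(1 for s in self.pav_stats if s.span_fallback)

    def present_ids(self) -> set[str]:
        return {s.gene_id for s in self.pav_stats if s.call == pav.PRESENT}

    def absent_ids(self) -> set[str]:
        return {s.gene_id for s in self.pav_stats if s.call == pav.ABSENT}

    def summary(self) -> dict:
        assert self.n_present + self.n_absent == self.n_genes_in_region
        return {
            "region": None if self.region is None else {
                "seq_id": self.region.seq_id,
                "start": self.region.start,
                "end": self.region.end,
                "length": self.region.length,
            },
            "n_genes_in_region": self.n_genes_in_region,
            "n_present": self.n_present,
            "n_absent": self.n_absent,
            "n_span_fallback": self.n_span_fallback,
            "n_clusters": len(self.clusters),
            "cluster_sizes": [c.n_absent for c in self.clusters],
            "n_rescued_unplaced": len(self.rescued),
            "rescued_gene_ids": sorted(s.gene_id for s in self.rescued),
            "arm_verdict": None if self.arm_assignment is None
            else self.arm_assignment.verdict,
            "marker_support": None if self.arm_assignment is None else {
                k: list(v) for k, v in self.arm_assignment.support.items()
            },
            "params": self.params,
        }


def intersect_region_genes(
    genes: Iterable[GeneModel],
    region: HighCoverageRegion,
    containment: bool = False,
) -> list[GeneModel]:
    """Genes whose span overlaps the region by at least one base.

    With ``containment=True`` a gene must lie entirely inside the region.
    Intervals are half-open, so a gene ending exactly at the region start
    does not overlap it.
    """
    out = []
    for g in genes:
        if g.seq_id != region.seq_id:
            continue
        if containment:
            keep = g.start >= region.start and g.end <= region.end
        else:
            keep = g.start < region.end and g.end > region.start
        if keep:
            out.append(g)
    return out


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def run(config: RunConfig) -> RunReport:
    """Execute the full analysis; writes artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info("parameters: %s", json.dumps(config.params_dict(), sort_keys=True))

    stage = "load-reference"
    try:
        lengths = formats.fasta_lengths(config.reference)
        logger.info("reference: %d sequences, %d bp total",
                    len(lengths), sum(lengths.values()))

        stage = "load-annotation"
        genes = formats.read_annotation(config.annotation,
                                        quality_key=config.quality_key)
        logger.info("annotation: %d genes (%d unplaced)",
                    len(genes), sum(1 for g in genes if not g.placed))

        stage = "depth"
        if config.alignments is not None:
            depth = coverage.compute_depth(
                formats.read_alignments(config.alignments, config.min_mapq,
                                        reference_lengths=lengths),
                lengths,
            )
        else:
            depth = formats.read_depth_table(config.depth_table, lengths)
        logger.info("depth: %d aligned bases total", depth.total())

        stage = "windows"
        target = config.target_seq or max(lengths, key=lambda s: lengths[s])
        all_windows = coverage.windowed_median(depth, config.window)
        coverage.write_windows_tsv(all_windows, outdir / "windows.tsv")
        target_windows = [w for w in all_windows if w.seq_id == target]

        stage = "delineate-region"
        region = coverage.delineate_high_coverage_region(
            target_windows, config.min_median, config.max_gap_windows
        )
        if region is None:
            logger.warning("no high-coverage region found on %s", target)
        else:
            logger.info("high-coverage region: %s:%d-%d (%d bp)",
                        region.seq_id, region.start, region.end, region.length)
            formats.write_bed(
                [(region.seq_id, region.start, region.end, "high_coverage_region")],
                outdir / "region.bed",
            )

        stage = "pav"
        placed = [g for g in genes if g.placed]
        in_region = (
            [] if region is None
            else intersect_region_genes(placed, region, config.containment)
        )
        stats = pav.call_genes(in_region, depth, config.default_thresholds)
        formats.write_pav_report(stats, outdir / "pav_report.tsv")
        n_present = sum(1 for s in stats if s.call == pav.PRESENT)
        logger.info("PAV: %d genes in region, %d present, %d absent",
                    len(stats), n_present, len(stats) - n_present)

        stage = "clusters"
        found: list[clusters_mod.AbsentCluster] = []
        if not config.skip_clusters and stats:
            found = clusters_mod.find_absent_clusters(
                stats, config.cluster_max_gap, config.cluster_min_size
            )
            formats.write_bed(clusters_mod.clusters_to_bed_rows(found),
                              outdir / "clusters.bed")
            clusters_mod.write_clusters_tsv(found, outdir / "clusters.tsv")
            logger.info("clusters: %s", [c.n_absent for c in found])

        stage = "rescue-unplaced"
        rescued: list[pav.GeneCoverageStat] = []
        if not config.skip_rescue:
            rescued = pav.rescue_unplaced(genes, depth,
                                          config.conservative_thresholds)
            formats.write_pav_report(rescued, outdir / "rescued_unplaced.tsv")
            logger.info("rescued %d unplaced genes", len(rescued))

        stage = "markers"
        assignment = None
        placements: list[armcheck.MarkerPlacement] = []
        skipped: dict[str, str] = {}
        if not config.skip_markers and config.markers is not None:
            markers = formats.read_markers(config.markers)
            ref_seqs = formats.read_fasta(config.reference)
            placements, skipped = armcheck.locate_markers(markers, ref_seqs)
            placements = armcheck.annotate_in_region(placements, region)
            assignment = armcheck.assign_arm(placements, region)
            armcheck.write_placements_tsv(placements, outdir / "marker_placements.tsv")
            logger.info("arm verdict: %s (support %s)",
                        assignment.verdict, assignment.support)
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    report = RunReport(
        region=region,
        pav_stats=stats,
        clusters=found,
        rescued=rescued,
        arm_assignment=assignment,
        marker_placements=placements,
        unplaced_markers=skipped,
        params=config.params_dict(),
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=1, sort_keys=True)
    return report


def _setup_logging(outdir: Path) -> None:
    if not logger.handlers:
        logger.setLevel(logging.INFO)
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(sh)
    for h in [h for h in logger.handlers if isinstance(h, logging.FileHandler)]:
        logger.removeHandler(h)
        h.close()
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
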