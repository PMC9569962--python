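"""Format boundary tests: coordinate conventions and lossless round trips."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from armpav import formats
from armpav.models import DepthTrack, GeneModel, MarkerRecord
from armpav.simdata import SimConfig, simulate_reference

from conftest import write_sam


GFF_ONE_GENE = """##gff-version 3
chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=geneA;annotation_quality=low
chr1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=geneA.1;Parent=geneA
chr1\tsrc\tCDS\t1\t30\t.\t+\t0\tID=cds1;Parent=geneA.1
chr1\tsrc\tCDS\t61\t100\t.\t+\t0\tID=cds2;Parent=geneA.1
"""


class TestAnnotation:
    def test_gff3_coordinates_become_zero_based_half_open(self, tmp_path):
        """A 1..100 gene with CDS 1..30 and 61..100 maps to [0,100) with CDS
        {[0,30),[60,100)} totalling 70 coding bases."""
        p = tmp_path / "one.gff3"
        p.write_text(GFF_ONE_GENE)
        (gene,) = formats.read_annotation(p)
        assert (gene.start, gene.end) == (0, 100)
        assert gene.cds_intervals == ((0, 30), (60, 100))
        assert gene.cds_length == 70
        assert gene.annotation_quality == "low"

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "empty.gff3"
        p.write_text("##gff-version 3\n")
        assert formats.read_annotation(p) == []

    def test_gene_without_cds_is_retained_with_empty_intervals(self, tmp_path):
        p = tmp_path / "nocds.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t11\t50\t.\t-\t.\tID=geneB\n"
        )
        (gene,) = formats.read_annotation(p)
        assert gene.cds_intervals == ()
        assert not gene.has_cds
        assert gene.stat_intervals() == ((10, 50),)

    def test_primary_transcript_isoform_selection(self, tmp_path):
        """Only the .1 transcript's CDS union is used; .2 is ignored."""
        p = tmp_path / "iso.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t200\t.\t+\t.\tID=g\n"
            "chr1\tsrc\tmRNA\t1\t200\t.\t+\t.\tID=g.2;Parent=g\n"
            "chr1\tsrc\tCDS\t1\t200\t.\t+\t0\tID=c2;Parent=g.2\n"
            "chr1\tsrc\tmRNA\t1\t200\t.\t+\t.\tID=g.1;Parent=g\n"
            "chr1\tsrc\tCDS\t11\t40\t.\t+\t0\tID=c1;Parent=g.1\n"
        )
        (gene,) = formats.read_annotation(p)
        assert gene.cds_intervals == ((10, 40),)

    def test_unplaced_inferred_from_sequence_name(self, tmp_path):
        p = tmp_path / "placed.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr7R\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "contig_9\tsrc\tgene\t1\t100\t.\t+\t.\tID=g2\n"
        )
        genes = {g.gene_id: g for g in formats.read_annotation(p)}
        assert genes["g1"].placed and not genes["g2"].placed

    def test_simulated_annotation_round_trip(self, tmp_path):
        """Write -> read on simulator output returns identical gene models."""
        ref = simulate_reference(SimConfig(
            seed=3, n_genes_arm=10, arm_len=100_000, offarm_len=50_000,
            other_seq_lens=(20_000,), unplaced_lens=(10_000,), n_unplaced_arm=1,
            deleted_blocks=(), interspersed_template=None,
            n_arm_markers=1, n_off_markers=1,
        ))
        p = tmp_path / "rt.gff3"
        formats.write_annotation(ref.genes, p)
        back = formats.read_annotation(p)
        assert back == ref.genes


class TestAlignments:
    def test_mapq_below_threshold_is_excluded(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", {"chr": 1000},
                        [{"seq_id": "chr", "pos": 0, "cigar": "50M", "mapq": 20},
                         {"seq_id": "chr", "pos": 0, "cigar": "50M", "mapq": 30}])
        recs = list(formats.read_alignments(sam, min_mapq=30))
        assert len(recs) == 1 and recs[0].mapq == 30

    def test_ungapped_match_interval(self, tmp_path):
        """150M at 1-based position 11 covers exactly [10, 160)."""
        sam = write_sam(tmp_path / "a.sam", {"chr": 1000},
                        [{"seq_id": "chr", "pos": 10, "cigar": "150M"}])
        (rec,) = formats.read_alignments(sam, min_mapq=0)
        assert rec.aligned_ref_intervals == ((10, 160),)

    def test_insertion_consumes_no_reference(self, tmp_path):
        """Mixed cigar with a 10 bp insertion: reference footprint is
        read length minus 10 (validated against pysam's own block walk)."""
        sam = write_sam(tmp_path / "a.sam", {"chr": 1000},
                        [{"seq_id": "chr", "pos": 5, "cigar": "60M10I80M"}])
        (rec,) = formats.read_alignments(sam, min_mapq=0)
        assert rec.reference_length == 150 - 10
        # pysam's block walk (which splits at the insertion) is the oracle:
        # merging its abutting blocks must give our intervals
        import pysam
        with pysam.AlignmentFile(str(sam)) as af:
            (a,) = af
            merged = []
            for s, e in a.get_blocks():
                if merged and s == merged[-1][1]:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            assert rec.aligned_ref_intervals == tuple(merged)

    def test_deletion_covers_reference_and_skip_splits(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", {"chr": 10_000},
                        [{"seq_id": "chr", "pos": 0, "cigar": "30M5D30M100N40M"}])
        (rec,) = formats.read_alignments(sam, min_mapq=0)
        assert rec.aligned_ref_intervals == ((0, 65), (165, 205))

    def test_secondary_and_unmapped_excluded(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", {"chr": 1000},
                        [{"seq_id": "chr", "pos": 0, "cigar": "50M", "flag": 256},
                         {"seq_id": "chr", "pos": 0, "cigar": "50M", "flag": 2048},
                         {"seq_id": "chr", "pos": 0, "cigar": "50M"}])
        assert len(list(formats.read_alignments(sam, min_mapq=0))) == 1

    def test_unknown_reference_sequence_is_an_error(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", {"chrX": 1000},
                        [{"seq_id": "chrX", "pos": 0, "cigar": "50M"}])
        with pytest.raises(ValueError, match="chrX"):
            list(formats.read_alignments(sam, min_mapq=0,
                                         reference_lengths={"chr": 1000}))


class TestDepthTable:
    def test_three_base_round_trip(self, tmp_path):
        track = DepthTrack({"s": np.array([5, 5, 5])})
        p = tmp_path / "d.tsv"
        formats.write_depth_table(track, p)
        assert p.read_text() == "s\t1\t5\ns\t2\t5\ns\t3\t5\n"
        assert formats.read_depth_table(p, {"s": 3}) == track

    def test_omitted_zero_positions_are_reconstructed(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("s\t2\t7\n")
        track = formats.read_depth_table(p, {"s": 4})
        assert track["s"].tolist() == [0, 7, 0, 0]

    def test_non_monotone_positions_rejected(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("s\t3\t1\ns\t2\t1\n")
        with pytest.raises(ValueError, match="monotone"):
            formats.read_depth_table(p, {"s": 5})

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 100), min_size=1, max_size=60),
           st.booleans())
    def test_randomized_round_trip(self, tmp_path_factory, depths, include_zeros):
        """Any depth vector survives write -> read unchanged, with or
        without explicit zero rows."""
        p = tmp_path_factory.mktemp("rt") / "d.tsv"
        track = DepthTrack({"seq": np.array(depths)})
        formats.write_depth_table(track, p, include_zeros=include_zeros)
        assert formats.read_depth_table(p, {"seq": len(depths)}) == track


class TestBedAndMarkers:
    def test_bed_is_zero_based_half_open(self, tmp_path):
        p = tmp_path / "r.bed"
        formats.write_bed([("seq", 0, 100)], p)
        assert p.read_text() == "seq\t0\t100\n"
        assert formats.read_bed(p) == [("seq", 0, 100, None)]

    def test_marker_round_trip_with_optional_fields(self, tmp_path):
        markers = [
            MarkerRecord("m1", "7RS", sequence="ACGTACGT"),
            MarkerRecord("m2", "7RL", seq_id="chr7R", pos=41),
        ]
        p = tmp_path / "m.tsv"
        formats.write_markers(markers, p)
        assert formats.read_markers(p) == markers

    def test_marker_without_sequence_or_position_rejected(self):
        with pytest.raises(ValueError):
            MarkerRecord("m", "7RS")


class TestGeneModelInvariants:
    def test_cds_outside_span_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "s", 10, 20, cds_intervals=((5, 15),))

    def test_overlapping_cds_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "s", 0, 100, cds_intervals=((0, 50), (40, 90)))
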