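"""Horizontal-coverage statistics, presence calls and unplaced-gene rescue."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from armpav.models import DepthTrack
from armpav.pav import (
    ABSENT,
    CONSERVATIVE_THRESHOLDS,
    DEFAULT_THRESHOLDS,
    PRESENT,
    PAVThresholds,
    call_presence,
    gene_coverage,
    rescue_unplaced,
)
from armpav.simdata import SimConfig, simulate_reads, simulate_reference
from armpav.coverage import compute_depth
from armpav.models import AlignmentRecord

from conftest import make_gene, make_track


def counting_oracle(gene, vec, min_depth):
    """Per-base loop, independent of the vectorized implementation."""
    above = total = 0
    values = []
    for s, e in gene.stat_intervals():
        for b in range(s, e):
            total += 1
            values.append(vec[b])
            if vec[b] >= min_depth:
                above += 1
    values.sort()
    n = len(values)
    med = values[n // 2] if n % 2 else (values[n // 2 - 1] + values[n // 2]) / 2
    return above, total, above / total, med


class TestGeneCoverage:
    def test_zero_depth_everywhere(self):
        gene = make_gene(cds=((0, 60),))
        stat = gene_coverage(gene, make_track(chr=np.zeros(100, dtype=int)))
        assert stat.horizontal_coverage == 0.0
        assert stat.median_depth == 0.0

    def test_uniform_38x_fully_covered(self):
        """A retained gene at the study's typical present-gene depth."""
        gene = make_gene(cds=((10, 90),))
        stat = gene_coverage(gene, make_track(chr=np.full(100, 38)))
        assert stat.horizontal_coverage == 1.0
        assert stat.median_depth == 38

    def test_six_of_hundred_bases_at_threshold(self):
        """Exactly 6 of 100 CDS bases at >=2X gives horizontal coverage 0.06."""
        vec = np.zeros(100, dtype=int)
        vec[40:46] = 2
        gene = make_gene(cds=((0, 100),))
        stat = gene_coverage(gene, make_track(chr=vec), min_depth=2)
        assert stat.bases_at_or_above == 6
        assert stat.horizontal_coverage == pytest.approx(0.06)
        oracle = counting_oracle(gene, vec, 2)
        assert (stat.bases_at_or_above, stat.cds_length,
                stat.horizontal_coverage, stat.median_depth) == oracle

    def test_statistics_cover_cds_union_only(self):
        vec = np.zeros(100, dtype=int)
        vec[0:30] = 10   # first exon covered
        vec[30:60] = 10  # intron covered too, must not count
        gene = make_gene(cds=((0, 30), (60, 100)))
        stat = gene_coverage(gene, make_track(chr=vec))
        assert stat.cds_length == 70
        assert stat.bases_at_or_above == 30

    def test_span_fallback_for_cds_less_gene(self):
        gene = make_gene(start=10, end=50, cds=())
        stat = gene_coverage(gene, make_track(chr=np.full(60, 9)))
        assert stat.span_fallback
        assert stat.cds_length == 40

    def test_missing_sequence_names_the_seq_id(self):
        gene = make_gene(seq_id="chrZ")
        with pytest.raises(KeyError, match="chrZ"):
            gene_coverage(gene, make_track(chr=np.zeros(10, dtype=int)))

    def test_matches_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(50, 300))
            vec = rng.integers(0, 8, n)
            k = int(rng.integers(1, 4))
            bounds = np.sort(rng.choice(n, size=2 * k, replace=False))
            cds = tuple((int(bounds[2 * i]), int(bounds[2 * i + 1]))
                        for i in range(k)
                        if bounds[2 * i] < bounds[2 * i + 1])
            if not cds:
                continue
            gene = make_gene(start=0, end=n, cds=cds)
            min_depth = int(rng.integers(1, 5))
            stat = gene_coverage(gene, make_track(chr=vec), min_depth)
            assert (stat.bases_at_or_above, stat.cds_length,
                    stat.horizontal_coverage,
                    stat.median_depth) == counting_oracle(gene, vec, min_depth)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 60), min_size=20, max_size=80))
    def test_horizontal_coverage_non_increasing_in_min_depth(self, depths):
        gene = make_gene(end=len(depths), cds=((0, len(depths)),))
        track = make_track(chr=np.array(depths))
        fracs = [gene_coverage(gene, track, d).horizontal_coverage
                 for d in (1, 2, 5, 10, 50)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestCallPresence:
    def test_boundary_more_than_five_percent(self):
        """0.05 is absent ("more than 5%"), 0.06 is present."""
        gene = make_gene(cds=((0, 100),))
        for frac, expected in [(0.05, ABSENT), (0.06, PRESENT)]:
            vec = np.zeros(100, dtype=int)
            vec[: int(frac * 100)] = 2
            stat = call_presence(gene_coverage(gene, make_track(chr=vec), 2))
            assert stat.call == expected, frac

    def test_zero_bases_above_threshold_is_absent(self):
        """The study's deleted block: zero bases over 2X forces absence."""
        stat = call_presence(
            gene_coverage(make_gene(), make_track(chr=np.ones(100, dtype=int)), 2)
        )
        assert stat.bases_at_or_above == 0
        assert stat.call == ABSENT

    def test_non_strict_comparator_includes_boundary(self):
        gene = make_gene(cds=((0, 100),))
        vec = np.zeros(100, dtype=int)
        vec[:5] = 2
        thr = PAVThresholds(2, 0.05, strict=False, name="ge")
        assert call_presence(gene_coverage(gene, make_track(chr=vec), 2),
                             thr).call == PRESENT

    def test_mismatched_min_depth_is_an_error(self):
        stat = gene_coverage(make_gene(), make_track(chr=np.ones(100, dtype=int)), 2)
        with pytest.raises(ValueError, match="min_depth"):
            call_presence(stat, CONSERVATIVE_THRESHOLDS)

    def test_call_reevaluates_consistently(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            vec = rng.integers(0, 10, 100)
            stat = call_presence(
                gene_coverage(make_gene(cds=((0, 100),)),
                              make_track(chr=vec), 2))
            assert (stat.call == PRESENT) == \
                DEFAULT_THRESHOLDS.present(stat.horizontal_coverage)


class TestRescueUnplaced:
    def make_unplaced(self, depth_value):
        gene = make_gene(gene_id=f"u{depth_value}", seq_id="contig_1",
                         cds=((0, 100),), placed=False)
        track = make_track(contig_1=np.full(100, depth_value))
        return gene, track

    def test_uniform_49x_not_rescued(self):
        gene, track = self.make_unplaced(49)
        assert rescue_unplaced([gene], track) == []

    def test_uniform_50x_rescued(self):
        gene, track = self.make_unplaced(50)
        (stat,) = rescue_unplaced([gene], track)
        assert stat.call == PRESENT and stat.horizontal_coverage == 1.0

    def test_placed_genes_are_ignored(self):
        gene = make_gene(seq_id="contig_1", cds=((0, 100),), placed=True)
        track = make_track(contig_1=np.full(100, 100))
        assert rescue_unplaced([gene], track) == []

    def test_conservative_present_subset_of_default_present(self):
        """Bases >=50X are a subset of bases >=2X and 0.95 > 0.05, so a
        conservatively present gene is always default-present too."""
        rng = np.random.default_rng(31)
        for _ in range(100):
            vec = rng.integers(0, 80, 120)
            gene = make_gene(end=120, cds=((0, 120),))
            track = make_track(chr=vec)
            cons = call_presence(gene_coverage(gene, track, 50),
                                 CONSERVATIVE_THRESHOLDS)
            default = call_presence(gene_coverage(gene, track, 2),
                                    DEFAULT_THRESHOLDS)
            if cons.call == PRESENT:
                assert default.call == PRESENT

    def test_simulated_arm_contig_rescued_contaminant_contig_not(self):
        """Unplaced contigs receiving arm-level depth are rescued; those
        receiving only contaminant background are not.  Simulated at high
        amplification so arm-level depth clearly exceeds the 50X rule."""
        config = SimConfig(
            seed=13, arm_len=200_000, offarm_len=200_000,
            other_seq_lens=(100_000,), unplaced_lens=(20_000,) * 4,
            n_unplaced_arm=2, n_genes_arm=40,
            deleted_blocks=(), interspersed_template=None,
            mean_depth=150.0, mda_sigma=0.2,
            n_arm_markers=1, n_off_markers=1,
        )
        ref = simulate_reference(config)
        reads = simulate_reads(config, ref)
        recs = [
            AlignmentRecord(
                f"f{i}", reads.seq_ids[i],
                ((int(reads.starts[i]), int(reads.starts[i]) + 150),
                 (int(reads.starts[i]) + 250, int(reads.starts[i]) + 400)),
                60)
            for i in range(reads.n_fragments)
        ]
        track = compute_depth(recs, ref.lengths())
        rescued = {s.gene_id for s in rescue_unplaced(ref.genes, track)}
        assert rescued == ref.truth.arm_unplaced_gene_ids

    def test_parameter_recovery_on_default_template(self, default_dataset,
                                                    default_report):
        """On the study template every deleted gene is called absent and
        every retained arm gene present: precision = recall = 1."""
        truth = set(default_dataset["truth"]["deleted_gene_ids"])
        assert default_report.absent_ids() == truth
        assert default_report.n_present + len(truth) == 200
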