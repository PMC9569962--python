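# Methods

## Analysis model

The pipeline treats an isolated-chromosome-arm sequencing experiment as a
coverage-comparison problem against a reference assembly.  Its stages, in
order:

1. **Alignment ingest.**  SAM/BAM records are reduced to their
   reference-consuming intervals under pileup semantics: M/=/X and D cigar
   operations cover reference bases, N splits an alignment into separate
   intervals, I/S/H/P cover nothing.  Unmapped, secondary and supplementary
   records are dropped, as are records with MAPQ < 30 (default).
   Duplicate reads are deliberately *kept*: the library is MDA-amplified,
   so duplicates carry real signal about amplification, and removing them
   would distort the depth distribution the thresholds were chosen for.
2. **Depth.**  Per-base depth is accumulated with a difference array
   (+1/−1 at interval ends, cumulative sum), which is exactly equivalent to
   per-position counting and O(reads + genome).  The conservation law
   Σ_b depth(b) = Σ_r reference-length(r) holds identically and is asserted
   in tests.
3. **Windowed medians and delineation.**  Depth is summarised as the median
   over consecutive 100-kb windows (the last window may be short and is
   kept — dropping it would silently truncate the chromosome).  Windows
   with median ≥ `min_median` (default 5X) are "high"; runs of high windows
   separated by at most `max_gap_windows` (default 10) low windows are
   merged, and the longest merged run — bounded by its first and last
   *high* window, ties to the leftmost — is the high-coverage region.  The
   defaults sit in the wide gap between present-gene depth (tens of X) and
   contaminant background (≈ mean_depth·(1−p)/(p·K) for purity p and a
   contaminant pool K-fold the arm; ≈ 1.8X under the default template), so
   the exact value is uncritical; both parameters are logged with every
   run.  Raising `min_median` can only shrink the region (property-tested).
4. **Presence/absence.**  Per gene, statistics are computed over the union
   of CDS intervals of the primary (".1") transcript; other isoforms are
   ignored.  Horizontal coverage is the fraction of CDS bases with depth at
   least `min_depth`; the median depth is taken over *all* CDS bases, zeros
   included, so fully missing genes report 0X.  The default call is
   present ⇔ horizontal > 0.05 at 2X — strictly greater, so a gene with
   exactly 5% qualifying bases is absent; the comparator is explicit and
   configurable.  The conservative rule for rescuing unplaced-contig genes
   is ≥ 0.95 at 50X (inclusive, "minimum").  Genes without CDS fall back to
   the gene span, are flagged `span_fallback`, and are excluded from
   headline counts.  Because bases ≥ 50X are a subset of bases ≥ 2X and
   0.95 > 0.05, conservative-present ⊆ default-present on any input.
5. **Clusters.**  Absent calls ordered by gene start are grouped by a
   greedy left-to-right scan that tolerates up to `max_gap` (default 5)
   consecutive present genes inside a cluster; clusters start and end on
   absent genes and need ≥ `min_cluster_size` (default 5) absent members.
   With `max_gap` 0 this reduces exactly to maximal runs of absent genes
   (oracle-tested).  The defaults resolve both canonical deletion shapes —
   a strict 7-gene run and a 65-of-81 interspersed region — as separate
   clusters while suppressing singletons.
6. **Arm identity.**  Markers are placed by exact substring search on both
   strands (optionally allowing substitutions); zero-hit markers are
   reported unplaced, multi-hit ambiguous; pre-aligned positions pass
   through.  Exact search is adequate for short diagnostic sequences and
   avoids an aligner dependency; real marker sets aligned elsewhere can be
   supplied as positions.  The verdict is the arm label with a strict
   majority of in-region placements and no more than `conflict_tolerance`
   (default 0) in-region placements of any other label; ties and empty
   input give "undetermined".
7. **Region–gene intersection** uses overlap by ≥ 1 bp on half-open
   intervals (a gene ending exactly at the region start is outside);
   full-containment mode is available since the choice is a genuine
   convention, with overlap as the default.

All internal coordinates are 0-based half-open; GFF3 and depth-table
(1-based) conversion happens only in `armpav.formats`, and every
reader/writer pair is a lossless round trip (property-tested).

## Synthetic data

`armpav.simdata` emulates the study design end to end.  The default
template scales a ~3,500-gene, several-hundred-Mb arm down to 200 genes on
a 1-Mb proximal arm of a 2-Mb pseudomolecule, plus two 750-kb background
sequences (the host genome contaminants come from) and six 20-kb unplaced
contigs, three of which truly belong to the arm.  Deletions follow the two
canonical shapes: one block of 7 consecutive genes, and one 81-gene window
in which 16 evenly interspersed genes are retained and 65 deleted.  Four
arm ("7RS") markers are planted uniquely inside the arm and two sister-arm
("7RL") markers in the off-arm half, alternating strands.

Reads are 150 bp paired-end fragments (insert 400 bp).  Each fragment is
arm-origin with probability `purity` (default 0.87); contaminant fragments
fall uniformly on the off-arm pool.  Arm fragments are sampled with
probability proportional to per-5-kb-locus log-normal(0, σ=0.5) factors —
an explicit stand-in for MDA amplification bias, which is strong and
locus-correlated but whose true form the kit does not specify — and never
overlap a deleted gene, so deleted genes receive exactly zero depth and
downstream absence calls are exactly recoverable.  The fragment count is
chosen so mean depth over non-deleted arm bases equals `mean_depth`
(default 30X).  Substitution errors are available (`error_rate`) but
default to 0, since alignments are emitted at the true origins regardless.
Reads are written as FASTQ and as perfect ungapped SAM alignments (MAPQ 60),
standing in for an external aligner.  Everything is a pure function of the
seed; identical seeds give byte-identical files.

What the simulation does **not** model: repeat content and mappability
(every position is uniquely alignable), alignment errors and chimeras,
indels, GC bias, or biased contaminant composition.  Passing tests
therefore demonstrate the correctness of the statistics and decision rules
given faithful alignments — not robustness to repeat-rich genomes or
aligner artifacts, where MAPQ filtering has to do real work.

A note on the conservative rescue rule: at 30X mean depth the 50X/95%
criterion is met only by loci whose MDA factor is well above average, so on
the default template the rescued set is a (possibly empty) subset of the
arm-member unplaced genes and contaminant-only genes are never rescued —
mirroring real data, where only a minority of truly present unplaced genes
clear 50X.  The discrimination property itself is tested at high simulated
amplification (150X mean, σ=0.2), where arm-member contigs clear the rule
decisively and the rescued set equals the truth exactly.

## Numerical and design choices

- Window medians use the standard middle-order statistic (mean of the two
  middle values for even counts), so half-integer medians are possible.
- `delineate_high_coverage_region` returns an explicit `None` (not an
  exception) when no window qualifies; the pipeline logs it and reports
  zero in-region genes.
- `call_presence` refuses a stat computed at a different `min_depth` than
  the thresholds — mixing regimes would silently corrupt the horizontal
  fraction.
- The annotation-quality attribute key defaults to `annotation_quality`
  with vocabulary high/low and default `high` for genes lacking the
  attribute; both are configurable because annotation releases differ.
  Gene placement is taken from an explicit pseudomolecule list when given,
  else inferred from the sequence name (contig/scaffold/chrUn ⇒ unplaced).
- Test and acceptance problem sizes (1–2 Mb genomes, 40–200 genes,
  10⁴–10⁵ fragments) are the package's chosen desk-scale working points:
  large enough for stable window medians and binomial checks on the
  contaminant fraction, small enough to iterate quickly.

## Known limitations

- The delineation rule is a reasonable reconstruction (threshold + gap
  merge); other rules (HMMs, changepoint detection) could place the
  boundary sub-window.  Accuracy here is asserted only to one window.
- Marker search is exact/Hamming; intron-spanning marker amplicons would
  need a real aligner and should be supplied as precomputed positions.
- CRAM is not supported; SAM/BAM only.
- Copy number, heterozygous presence/absence and conserved-domain
  annotation of absent genes are out of scope.
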