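# Methods

## Signal model and assumptions

The caller consumes probe-level normalized log ratios (NLR = log ChIP/input
after array normalization) and treats them as given: no error model,
background subtraction or replicate merging is applied upstream of
segmentation. The only distributional assumption is qualitative — histone
presence yields predominantly positive NLR, depletion predominantly
negative — which is what makes a sign-based rule sensible at 50-bp probe
resolution. All coordinates are 0-based half-open throughout; GFF3 input is
shifted on read and never seen downstream. Chromosomes are processed
independently.

## The segmentation procedure

Per chromosome, sorted probes are partitioned left-to-right into groups of
`group_size` = 5; the partition (and later any block) restarts whenever
`next.start − prev.end` > `max_gap` = 200 bp. End-to-start distance is the
right gap measure for overlapping tiling: with 60-mer probes at a 50-bp
step the covered-region gap is −10 bp, so the rule fires only at
repeat-masked holes. Trailing partial groups are retained and classified by
the same absolute rule — at least `low_neg_count` = 3 probes with strictly
negative NLR make a group *low* — so a group of ≤ 2 probes can never be
low; NLR exactly 0 is non-negative (the rule is strict).

Blocks open at a low group, absorb interior high runs shorter than
`stop_high_run` = 2, and close when a run reaches that length or a gap
break intervenes; the terminating run is excluded and the block is
right-trimmed to its last low group. This makes a block exactly a maximal
segment that starts and ends low and contains no high run of length ≥ 2 —
the property the test suite checks by exhaustive enumeration of all
low/high strings up to length 12. Blocks with fewer than `min_groups` = 2
low groups or spanning under `min_span` = 500 bp are dropped. The 500-bp
floor encodes the observation that the smallest credible call at this
geometry is ten contiguous probes, spanning 60 + 9 × 50 = 510 bp; an HFR's
size is its genomic span (first-probe start to last-probe end), including
any interior masked stretch of ≤ 200 bp, not just probe-covered bases.

Cross-array consistency flags an HFR *unenriched* in another antibody's
track iff the mean NLR of overlapping probes is < 0 **and** ≥ 50 % of those
probes are negative; both thresholds are exposed because "consistently
poor enrichment" admits more than one formalization. HFRs without
overlapping probes in a track are excluded from the summary denominator
with a warning.

## Annotation

Context is resolved in fixed precedence Genic ▸ TSS ▸ 3′ end ▸ NCT ▸
Intergenic. Genic uses the HFR *midpoint* (not any-overlap) so an HFR
touching a gene edge falls to the TSS or 3′-end class — the catalog treats
these as mutually exclusive labels. TSS and 3′-end windows are ±1 kb around
the strand-resolved transcription start/end; the 3′ window mirrors the TSS
window because no separate figure is established for it. CpG-island overlap
is reported as a boolean flag, not a context. Naming is purely positional:
`{cluster}_{left}-{right}.{k}` between genes (ordinals of the flanking
genes, k counting left→right), `{cluster}_{ordinal}.{k}` inside a gene, and
`UP`/`DOWN` affixes beyond the outermost genes, UP on the side of the
highest paralog ordinal. The packaged reference catalog normalizes the
handful of `A.UP.n`-style separators in the published table to the
dominant `A_UP.n` form.

## Motif scanning

Hits are exact string matches of the pattern (default GAGAG) on the plus
strand and of its reverse complement on the minus strand, reported on
plus-strand coordinates; N never matches. Tandem runs (GAGAGAG…) make the
counting policy material: the default is greedy non-overlapping per strand,
with an overlapping policy available, and the choice is recorded in
provenance because published motif totals rarely state it. Counts
deduplicate identical plus/minus coordinates (impossible for GAGAG, which
is not its own reverse complement, but enforced generally). Display-level
merging of hits within 20 bp never feeds back into counts.

## Assay analysis

Each replicate count is divided by its own biological batch's mean
empty-vector count; percent survival is 100 × the mean of these ratios
across all replicates and batches (so rescaling a batch changes nothing),
and the reported SE is the standard error over the same ratios — over all
6 ratios in the canonical 2-batch × 3-replicate design. The vector control
is 100 % by construction. Significance against the vector uses the classic
pooled-variance unpaired t test (df = n₁ + n₂ − 2), on ratios by default
with a raw-counts option. Tier bounds 50/65/75 encode the anchor
behaviours of the controls (strong blockers at 38–50 % survival, control
boundaries near 53 %, non-blockers ≥ 85 %).

Calibration of the estimator is defined against its *sampling* SE: over
500 simulations at a fixed survival fraction, the estimate must fall
within 2 standard deviations of the 500-run estimate distribution at least
95 % of the time (a 2-SD band around a near-Gaussian unbiased estimator
covers ≈ 95.4 %). The per-run reported SE is not usable for this purpose:
with n = 6 ratios a ±2-SE band is a ~90 % t-interval by construction, and
the shared per-batch vector denominator correlates ratios within a batch,
lowering it further — so a 95 % coverage requirement can only refer to the
sampling SE.

## What the generator emulates — and what it does not

`simulate_cluster` reproduces the array design: a 150-kb region, 60-mer
probes at a 50-bp step (≈ 3,000 probes), ~5 % of the region in masked
holes whose probes are omitted, eight planted depleted regions of
600–1,500 bp, and per-antibody NLR drawn N(+1, 0.4) outside and N(−1, 0.4)
inside planted regions. Planted intervals are snapped to the probe lattice
(start on the step grid, end offset by probe_length mod step), making each
exactly the union of the probes it contains; sizes then take the array's
natural 60 + 50 k values and the recoverable boundary is well defined —
group-phase effects bound the caller's boundary error at ≤ 100 bp absent
noise flips. Masked holes are drawn ≥ 300 bp clear of planted regions so
ground truth stays unambiguous. Genes are laid out on a regular grid with
jitter and planted regions are *placed from* their intended contexts
(inside a body, abutting a TSS/3′ window, under an emitted noncoding
transcript, or mid-gap), which is verified at generation time. Sequences
are i.i.d. bases at the configured GC content with planted GAGAG/CTCTC
motifs; chance occurrences of the pattern are scrubbed by point mutation so
the motif truth is exact. Colony counts are Poisson around
base_rate × batch_effect × survival with a log-normal batch effect
(σ = 0.15), base rate 200.

Real arrays differ in ways the generator deliberately ignores: spatially
correlated probe noise and dye bias, sequence-composition effects on
hybridization, partial (fractional-occupancy) depletion, repeat-driven
probe spacing irregularities, and biological coupling between motifs,
accessibility and depletion. Passing the recovery and calibration tests
therefore demonstrates correctness of the algorithms under the stated
noise model, not performance on any particular real array.

## Numerical and degenerate-input choices

Duplicate probe coordinates are a hard error (averaging would silently
change caller behaviour); unsorted input is sorted with a logged notice;
empty tracks yield empty catalogs. Probes must carry finite NLR. Overlap
uses half-open semantics with a ≥ 1-bp default (configurable minimum).
Batches lacking the vector control are an error at read time; a construct
absent from one batch simply contributes no ratios from it, with a
warning. Zero-variance t-test inputs return t = 0, p = 1 through the
underlying scipy routine.

## Problem sizes

Default test and reproduction scales: exhaustive caller oracle to label
strings of length 12 (8,190 cases), 1,000 random kilobase sequences for
the motif oracle, one 150-kb simulated cluster (≈ 3,000 probes) for
recovery, and 500 simulations per survival level for calibration. These
sizes make every property deterministic to check in seconds while keeping
the statistical checks (≥ 7/8 recovery, ≥ 95 % coverage) meaningful.

## Known limitations

The caller's boundary precision is one probe group at worst (two probe
steps); single-probe noise flips adjacent to a region edge can shift a
boundary by up to ~150 bp or split a call. Context labels are
single-valued by design and hide multi-feature overlaps beyond the CpG
flag. The reference catalog ships without genomic coordinates (the
published table has none), so coordinate-level comparisons against it are
out of reach. Reproducing the published genome-scale figures (93 HFRs, 113
GAF motifs, 82 % HS overlap) requires the deposited array data, the mm9
reference sequence and the original annotation tracks; the package's
algorithms accept exactly those inputs, but the repository does not bundle
them.
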