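# Methods

## The signal model

Read depth per non-overlapping bin is treated as a count whose expectation
is proportional to the local absolute copy number: an autosomal diploid bin
of average GC draws `depth × multiplier` reads, and a bin at copy number *c*
draws `c/2` times that. All samples are female, so the baseline is 2 copies
on autosomes and 1 on chrZ; chrZ bins therefore draw half the autosomal
depth, and the copy-number estimator for any region is

    CN = 2 · (mean corrected RD over the region's non-gap bins) / (diploid RD level)

on every chromosome — ploidy enters only when classifying a copy number as
gain or loss and when setting expected levels for significance tests.

## GC correction

Sequencers over- or under-sample fragments by GC content. Correction
rescales each bin by `m / m_GC`, where `m_GC` is the mean raw count of
non-gap autosomal bins in the same 1% GC stratum and `m` the corresponding
global mean; strata with fewer than 100 bins fall back to `m` (no
correction).

Two numerical points matter at small genome sizes. First, GC varies slowly
along the genome, so the bins of one CNV concentrate in very few strata and
drag those stratum means toward the event's copy number; plain stratum means
then over-correct the event (we observed distortions up to ~10% on 10 Mb
genomes) and leak bias into neutral bins. The strata are therefore
re-estimated after masking 1 kb windows whose mean deviates more than 25%
from the diploid level (mask dilated by one window to catch event edges),
iterating until the mask stabilizes (≤4 passes). 1 kb windows average
enough bins that the 25% threshold is ~2.5σ of counting noise yet still
trips on minimum-length events. Second, the *diploid RD level* that anchors
all CN ratios is not the plain mean (CNVs would inflate it) but a trimmed
mean of 5 kb window means: starting from the median, windows within a band
of ±4 robust SDs (MAD-based, capped at ±25%) are averaged, iterated five
times. On noise-free input this collapses to the exact neutral level, so
genotyping round-trips are exact.

Correction always starts from the raw channel, hence it is idempotent; it
preserves the plain global mean to within 1%.

## Segmentation

Mean-shift segmentation uses a positional shift vector per bin,

    shift_i = Σ_{d=1..3h} d · e^{−d²/(2h²)} · [K(x_{i+d}−x_i) − K(x_{i−d}−x_i)],
    K(δ) = e^{−δ²/(2s²)},

with spatial bandwidth *h* and signal bandwidth *s* = √(diploid level), the
Poisson noise scale. Inside a homogeneous segment the pulls balance; the
last bin of a segment is pulled left and the first bin of the next pulled
right, so boundaries are placed where the shift changes sign from negative
to positive. The procedure runs over a doubling bandwidth schedule
(2, 4, …, 128 bins). After each pass, adjacent segments merge when a Welch
t-test on their member bins cannot tell them apart; because mean-shift puts
boundaries where the contrast is locally most extreme, the test threshold is
selection-corrected — a pair stays split only when `p ≤ 0.01 / (2·min(n₁,n₂))`
— otherwise noise-selected splinters inside genuine events survive
indefinitely. The working signal is then replaced by segment means so fine
boundaries persist through coarse passes. Finally every boundary is refit by
exhaustive two-rate quasi-Poisson change-point search over its adjacent
segment pair (alternating with merging until stable); the likelihood form
weights the low-copy side more, which is correct for counts.

Gap bins are masked; each maximal gap-free run is segmented independently,
so segments partition the non-gap bins exactly.

## Calling and filters

A segment is a candidate CNV when its mean leaves ±25% of its chromosome's
expected neutral level. Contiguous same-direction candidates coalesce into
one candidate with statistics refit from the pooled bins — a long event
often segments into pieces of slightly different level, and all its pieces
clear the gate. Each candidate carries a two-sided one-sample t-test of its
bins against the expected level, the CN estimate above, and the
read-weighted q0 fraction. The filters retain a call iff p < 0.01 AND
length > 1 kb AND q0 ≤ 0.5 AND no assembly-gap overlap (a raw mode keeps
gap-spanning calls for re-inspection of known loci); every rejection is
logged with all failing reasons. Surviving same-type calls separated only by
gap bins merge into one call.

## Validation procedures

*Digital aCGH.* For a (test, reference) pair, overlapping calls are cut at
every call boundary into disjoint subsegments and unique calls kept whole;
segments ≤1 kb are dropped. Each segment's `log2(CN_test/CN_ref)` (zero
copies floored at 0.5 to keep the ratio finite and monotone) is compared to
the mean probe log2 ratio over the same span by Pearson correlation and
ordinary least squares; the mean of the probe values is reported alongside,
since a global offset there indicates array bias rather than calling error.

*qPCR.* Replicates are averaged on the Ct scale; `ΔCt = Ct_target −
Ct_control`, `ΔΔCt` is taken against a reference sample that is copy-neutral
at the locus, and `CN = ploidy_ref · 2^(−ΔΔCt)` (the textbook `2^(1−ΔΔCt)`
on autosomes). Copy numbers ≥2.5 count as gains and ≤1.5 as losses (halved
on a female Z); the midpoint cuts are a package choice, exposed as
parameters. Confirmation is scored as the positive predictive value
(confirmed / predicted-positive) and the false-negative rate
(qPCR-positive / predicted-negative), reported per region, as unweighted
region averages, and sample-pooled — the averaging convention is ambiguous
in the field, so both are printed.

*Neutral-region QC.* All autosomal 5 kb windows clear of calls and gaps are
genotyped; per-sample mean and STDEV should bracket 2 copies tightly (the
field's rule of thumb places neutral regions between 1.5 and 2.5 copies).

## Clustering

Copy number of 1 kb windows across a gene ±30 kb flanks, all samples.
Distance is 1 − Pearson r between sample rows (zero-variance rows are
assigned the maximum distance 2 and flagged; Pearson is undefined there).
Agglomeration is unweighted average linkage with a deterministic tie-break
(lowest-index pair first); leaf order follows the merge tree with the
lower-index branch left, so outputs are reproducible. Windows are never
reordered. The heatmap colour scale is linear from 0 to a configurable
ceiling (default 8 copies) to keep mid-range contrast.

## The synthetic cohort

Defaults emulate the study design this package targets: 12 female samples,
one 10 Mb autosome at 100 bp bins, ~10 reads per bin (≈10× with 100 bp
reads) with per-sample depth multipliers drawn from 0.8–1.25 (the 8.2–12.4×
spread of real cohorts), Poisson counting noise (negative-binomial and
noise-free switches available), a quadratic GC bias peaking at GC 0.45
(floored at 0.1), ~1% of the genome in bin-aligned gaps, background q0
fraction 0.02 rising to 0.8 in designated repeat intervals, and 30 events
per sample with log-uniform lengths 2–50 kb, CN ∈ {3,4,6} for gains and
{0,1} for losses, gains at 55% (real cohorts skew toward gains). Events are
bin-aligned, avoid gaps and keep ≥1 kb separation within a sample — the
unit of simulation is the bin, so sub-bin breakpoints are not modelled.
aCGH probes sit every 700 bp (skipping gaps) with Gaussian noise SD 0.2;
qPCR produces triplicate Ct values with noise SD 0.1 and efficiency 2.

What the generator does **not** emulate: real mappability structure (q0 is
an i.i.d. fraction, not alignment-derived), insert-size effects of
paired-end libraries, non-integer somatic mixtures, reference errors, or
inter-chromosomal variation in GC bias. Passing tests therefore demonstrate
correctness of the algorithms under the stated noise model, not performance
on real libraries.

## Accuracy at the study's depth, and a known limitation

On the noise-free cohort the caller emits exactly the embedded events >1 kb
with exact breakpoints and CN — the round-trip identity the tests assert.
Under Poisson noise at ~10×, detection of events ≥5 kb is essentially
complete and the CN estimator is unbiased to well under 0.1 copies, but
breakpoint localization at *low-contrast* edges (one-copy steps: CN 1 or 3
against a diploid background, a jump of ~1.6 bin-level noise SDs) is limited
by the information in the data: even an ideal change-point estimator that
knows the true segment levels misses the ±2-bin window a substantial
fraction of the time at this depth. The pipeline sits close to that
estimator ceiling; the corresponding strict acceptance test (95% of events
with both edges within 2 bins) documents the gap rather than hiding it.
High-contrast edges (CN 0, 4, 6) localize within 1–2 bins almost always.

## Problem sizes

The test suite and the acceptance script run the full study at 10 Mb × 12
samples (about half a minute end to end) and smaller 2–4 Mb cohorts for
module tests — sizes chosen so a laptop reproduces everything in minutes
while every stage still sees realistic bin counts (10⁵ bins per sample) and
event mixtures.
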