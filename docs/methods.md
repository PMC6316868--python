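# Methods

## Coverage model and assumptions

The analysis compares a B-carrying female against a B-lacking (NoB) male
reference, both aligned to the same A-genome reference. The model assumes:

* the A genome is diploid in both samples, and the B is haploid (one per
  cell) unless `b_ploidy` is raised;
* B-derived reads map onto their A-genome homologs, so a segment with *c*
  B-located copies elevates the female's expected depth by a factor
  (2 + *c*)/2 relative to her diploid baseline;
* depth inputs are already deduplicated — PCR-duplicate marking is an
  upstream alignment-side concern, and the package's contract begins at
  per-base depth;
* scaling by each sample's genome-wide mean removes library-size
  differences, making the scaled coverage ratio (SCR) unit-free and
  invariant to rescaling either sample's depths.

A consequence of genome-mean scaling worth stating explicitly: B-derived
reads are part of the female's genome-wide mean, so every scaled value —
and every SCR — is deflated by a factor equal to one plus the B-derived
fraction of her read mass. In real data that fraction is a few percent and
the bias is correspondingly small, but it grows with the fraction of the
genome that is B-homologous. Copy numbers estimated from SCR inherit the
bias (estimates sit a few percent below truth); the package reproduces
this behaviour rather than correcting it, because the correction would
require knowing the B content being estimated.

## The per-base test

Coordinates are 0-based half-open internally; 1-based depth TSVs are
converted on read. Each base is scored with:

* `SCR = female_scaled / male_scaled`, with two sentinels: +inf when only
  the female has coverage (passes any SCR threshold; the count test still
  gates it) and 0 when neither does;
* a one-sided upper-tail binomial test on raw counts, X female reads of
  n = female + male, success probability p = female mean depth / (female
  + male mean depths), fixed genome-wide. One-sided because only SCR ≥ 3
  positions are ever kept — a lower-tail deviation cannot co-occur with an
  elevated ratio, and a two-sided test would only double the p-values of
  kept positions. The tail is evaluated through the regularized incomplete
  beta function (stable to n well beyond 10,000) and verified in tests
  against exact integer-rational summation of the mass function.
* No multiple-testing correction is applied across bases: the fixed
  p ≤ 0.001 per-base cutoff is part of the published procedure being
  implemented, and the downstream merge/length/fraction filters are the
  error control.

## Block calling

Defaults: SCR ≥ 3, p ≤ 0.001 (both inclusive, as printed), merge gap
300 bp (inclusive: exactly 300 bp apart merges), then removal of blocks
≤ 500 bp and of blocks with ≤ 10% of spanned positions passing — so
retained blocks are ≥ 501 bp with fraction strictly above 0.10. A block
spans first-to-last passing base, matching merge-of-single-base-features
semantics (cross-checked against `bedtools merge -d 300` in tests), not
extended by half-gaps. The passing fraction is computed over the final
block span. Block-level SCR is the ratio of block-mean scaled coverages,
not the mean of per-base ratios: per-base male zeros would contaminate a
mean of ratios, and the ratio of means is what the copy-number estimator
inverts.

## Copy number and length accounting

`copies = SCR × 2 − 2` when the block's mean male scaled coverage is ≥ 1
(inclusive); otherwise the male is assumed to represent one poorly-mapped
single-copy locus and `copies = female_scaled × 2`. The switch sits at
exactly 1, which is also the expectation in clean regions — so in
simulations the branch taken there is effectively a coin flip, and the two
estimators disagree by exactly 2 copies (the subtracted A-pair
contribution). This discontinuity is a property of the published estimator
pair, preserved deliberately. Estimates stay fractional in all sums;
negative values (possible for re-quantified core intervals with SCR < 1)
clamp to 0.

Core blocks are the maximal runs of bases covered by called blocks in
≥ k of N B-carrying samples, computed at base resolution with per-sample
presence/absence profiles (a sample with overlapping blocks still counts
once). No re-merge or length re-filter is applied, so core intervals may
be shorter than any single-sample block. Core intervals carry no global
copy number: each sample re-averages its own scaled coverages over every
core interval before estimating copies, so "core blocks in B space" is a
per-sample quantity. k is a free parameter (`core_k`), defaulting to
N − 1 carriers.

Gene overlap is gene-level: any annotated gene with ≥ 1 bp of overlap
with the block footprint is reported, "complete" when the union of blocks
contains it. Overlaps confined to introns are flagged and logged — they
may reflect a repeat insertion on the B rather than a B-located gene
copy — but are still counted, reproducing rather than correcting the
gene-level semantics.

## The simulator

`simulate_pair` draws integer depths around expected values given by the
coverage model: male = mean_depth_male everywhere; female =
mean_depth_female × (2 + b_ploidy·c)/2 inside planted segments, × 2 inside
A-genome duplications, baseline elsewhere. Mappability dropouts scale both
samples (pushing the male's scaled coverage below 1 to exercise the
female-only estimator); `true_retrogene` artifacts elevate the female over
exons only, `divergent_intron` artifacts elevate both samples over a whole
gene. Noise is Poisson by default; `negative_binomial` (gamma-Poisson,
var = μ + 0.1 μ², dispersion configurable) models the overdispersion of
real Illumina depth; `"none"` gives rounded expectations for noise-free
limit checks. Default depths are 15× (female) / 25× (male), typical of the
individual-female and pooled-male sequencing runs this analysis is built
for. The simulator writes the same depth-TSV dialect the pipeline reads.

What the simulator does **not** emulate: read-level artifacts (mapping
quality, soft-clipping), GC- or repeat-driven coverage waves, sequence
divergence between B and A copies, or B sequence with no A-genome homolog
(which the coverage-ratio method is mechanistically blind to). Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the stated coverage model, not robustness to every
alignment pathology of real data.

## The recovery benchmark

`recovery_benchmark_config` is the package's canonical parameter-recovery
scenario: a 2 × 1 Mb genome with 20 planted segments of 1–20 kb and 4–50
copies at Poisson 15×/25×. The frozen segment table skews lengths small
(most near 1–1.5 kb, median well under 2 kb — the shape real B-block size
distributions take) and places the highest copy numbers on the shortest
segments, keeping planted B-derived reads at ~12% of the female's read
mass. That choice is deliberate: the coverage-ratio method assumes B
content is a modest fraction of the read mass (see the genome-mean bias
above), and a miniature genome in which planted segments dominated the
read mass would exercise a regime the method is not meant for — c = 4
segments would drop below the SCR ≥ 3 threshold entirely. At this scale
the residual bias is visible but bounded: mean copy-number error for
≥ 2 kb segments stays within 15%, and summed B-space within 20% of truth.
Problem sizes throughout the test suite (0.2–2 Mb genomes) were chosen as
the smallest scale at which per-base Poisson statistics are stable enough
for these bounds.

## Numerical and degenerate-input choices

* Bases absent from a depth file are depth 0, and zeros count toward the
  genome mean (excluding them would inflate the scaling denominator).
* A sample with zero total depth is an error ("empty coverage"); an empty
  block set quantifies to an all-zero report with an undefined core
  percentage (reported as NA/None, never 0/0).
* Depth-track means recomputed on load must match any user-supplied value
  within 1e-6 relative; block BED floats are written with full `repr`
  precision so write → read round trips are bit-exact.
* Interval engines (gap merge, k-of-N intersection) are exact integer
  algorithms verified against naive per-base oracles; ties are inclusive
  (merge at exactly the gap, estimator switch at exactly 1, thresholds at
  exactly SCR = 3 and p = 0.001) matching the published wording.

## Known limitations

* The per-base binomial test treats neighboring bases as independent,
  which read length makes false; the merge/filter stages absorb most of
  the resulting clustering of false positives, as the control simulations
  show, but footprint-level false-positive rates are not analytically
  controlled.
* Copy-number estimates inherit the genome-mean deflation bias described
  above, and the Eq3/Eq4 switch is discontinuous at male scaled
  coverage 1.
* Sequence unique to the B, and B segments with fewer than 4 copies,
  are undetectable by design (SCR < 3).
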