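# Methods

This note documents the models, parameter choices and numerical
conventions behind `embryoscreen`, and what the synthetic data do and do
not establish about behaviour on real sequencing data.

## Signal model

A trophectoderm biopsy yields a few cells; after whole-genome
amplification and shallow single-end sequencing, the read count of a
genomic bin is modelled as

    C_k ~ overdispersed count,  E[C_k] ∝ (q_k / 2) · w(gc_k)

where `q_k` is the local integer copy number (2 on autosomes of a normal
cell; X and Y follow the embryo's sex) and `w(gc)` is a smooth
amplification-bias weight induced by WGA. Everything downstream —
GC correction, normalisation to `cn` ratios with autosomal median 2,
segmentation, dynamic-threshold calling — is a sequence of estimators for
`q` under this model. Mosaicism, polyploidy and balanced rearrangements
are outside the model: a count-based shallow-WGS profile cannot see
balanced translocations at all, and a persistent non-integer level
between the calling thresholds is silently treated as diploid (a
documented limitation, not an error).

## Binning and coordinates

* Bin size defaults to 1,000,000 bp. At study-scale depth (8.2 M reads on
  a ~3.1 Gb genome) this gives ≈ 2,700 reads per bin, i.e. a per-bin
  counting CV of ~2%, which supports the ≥ 1 Mb calling resolution with
  high signal-to-noise. The bin size is configurable; all length-based
  defaults (minimum call length 1 Mb) are in base pairs, not bins.
* Coordinates are 0-based half-open internally; BED input is consumed
  as-is and SAM positions are converted. Reads are assigned to bins by
  start position only — single-end reads are two orders of magnitude
  shorter than a bin, so fractional-overlap assignment would change
  nothing measurable.
* The mitochondrial contig stays off the bin grid. Its mean depth
  (reads × read length / 16,569) over the nuclear mean depth is the
  relative mtDNA copy number; with default parameters the contig is
  essentially fully covered, matching the near-complete mtDNA coverage
  expected at these depths.

## GC correction

The count-vs-GC trend `f̂` is fitted on autosomal bins with local-linear
LOESS (robustifying iterations, span default 0.3) plus one Tukey twicing
pass — the residuals are smoothed once more and added back — which
removes most of the local-linear curvature bias where the trend is
strongly convex. Corrected counts are `c_k / f̂(gc_k)`, rescaled to
preserve the total count exactly. Outside the fitted GC support the
nearest edge value is used. Genomes under 200 bins fall back to GC-decile
medians, which need no tuning at sizes where LOESS is unstable. A
degenerate GC track (range < 0.001) makes the correction an identity,
with a warning. The span trades bias against variance: 0.3 is appropriate
for noisy WGA data, while noise-free validation profiles are best fitted
near 0.15 (the test suite does exactly that when asserting ≤ 1% residual
flatness on a known injected curve).

## Segmentation and stopping

Per chromosome, segments are split recursively at the maximiser of the
t-like statistic `T(i)` (pooled-SD normalised mean difference; ties break
toward the smallest index; a zero pooled SD with unequal means counts as
an infinitely strong split). A split must beat the (1−α) quantile of the
max-|T| over within-segment permutations (α = 0.01, 1,000 permutations,
seeded; measured false-split rate on pure noise ≈ 1% per series). When
the single split is rejected, the best interior window against the rest
is tested with the same permutation rule — the circular (double-cut)
refinement familiar from CBS. This is essential, not cosmetic: a single
split has almost no power against an event embedded mid-segment, because
the event inflates both the pooled SD and the permutation null. The two
tests per segment bound the per-segment type-I error by 2α. Recursion
stops at segments of fewer than 2 × `min_seg_bins` (default 3) bins or at
depth 20. With `n_permutations = 0` acceptance is deterministic (any
strictly positive statistic splits) — only meaningful on noise-free
input, where it reproduces the exhaustive least-squares changepoint
solution.

## Dynamic thresholds and calling

Calling cuts are `2 ± max(0.4, 3 · MAD/√min_seg_bins)`, where MAD is the
1.4826-scaled median absolute deviation of autosomal `cn` ratios: the
deviation term is the noise of a minimum-size segment mean, so noisier
WGA samples require larger deviations, while the 0.4 floor keeps
sub-mosaic wobble from being called in very quiet samples. Sex
chromosomes are excluded from the median and MAD so an XY sample's halved
X signal cannot shift the autosomal baseline, and their calling baseline
follows the inferred sex (X/Y medians against midpoint cutpoints 1.5 and
0.5; exact boundaries are undetermined, and undetermined sex disables
sex-chromosome calling rather than guessing). Threshold-passing adjacent
same-direction segments merge; copy number is the bin-weighted mean
rounded and clamped to [0, 4] — shallow coverage cannot reliably resolve
higher states — and a call whose rounded copy number equals its baseline,
or which is shorter than 1 Mb, is dropped. A call covering ≥ 90% of its
chromosome is "whole-chromosome"; the 90% boundary between numerical and
segmental aberrations is a package choice (no standard definition
exists) and is recorded on every call.

Output nomenclature is 1-based inclusive (`seq {chrom}{band} →
{band}({start}–{end})×{n}`), with `pter`/`qter` for terminal bands,
matching clinical sequencing-karyotype reports; internally everything
stays 0-based half-open, and `parse_call` inverts `format_call` exactly.

## Statistics

* Mann–Whitney U (mtDNA ratios, euploid vs any chromosomal abnormality):
  two-sided; exact enumeration when both groups have ≤ 8 tie-free
  observations, otherwise normal approximation with tie and continuity
  corrections. Two-sidedness is an assumption; the implementation is
  verified against complete enumeration of the permutation null on all
  small rank patterns.
* Pearson chi-squared on 2×2 outcome tables: margin-derived expectations,
  1 df, **no** Yates continuity correction — the convention under which
  the implementation reproduces the published clinical outcome p-values
  to 3 decimals (with correction it does not). Rates follow the standard
  denominators: pregnancies and ongoing pregnancies per transfer cycle,
  miscarriages per clinical pregnancy, implantations per embryo
  transferred. Twin pregnancies and per-couple clustering are not
  modelled; rates are computed on aggregated counts.

## Synthetic data: what it emulates, what it does not

The generator produces a human-like genome (default: 8 autosomes of
45–24 Mb plus X and Y, ~321 Mb total, 1 Mb bins), a smooth sinusoidal GC
track clamped to [0.25, 0.65], per-arm cytobands with a centromere at
40% of each chromosome, and read sets with:

* study-scaled depth — 8.2 M reads per sample scaled by genome size
  (~850k reads, preserving ~2,700 reads/bin);
* a unimodal quadratic GC-bias weight `w = max(0.1, 1 − 6(gc − 0.45)²)`
  (the real WGA bias shape is not published; the curve is a documented
  free choice, and its parameters, peak and curvature, are test inputs,
  not fitted constants);
* negative-binomial per-bin counts with variance `μ + 0.0025 μ²` (~5%
  extra CV, a WGA-like noise floor; 0 gives Poisson), scattered
  uniformly into read positions within each bin — identical first and
  second bin-level moments to a per-read sampler at a fraction of the
  cost, while still exercising the binning stage end to end;
* mitochondrial reads at an expected depth ratio of 100× the nuclear
  depth (the absolute scale of blastocyst mtDNA ratios is
  sample-dependent; 100 is a round documented default), multiplied by a
  per-embryo lognormal factor (σ = 0.5) and by 1.3 for chromosomally
  abnormal embryos — the direction reported for real blastocysts; the
  effect size is a package choice, so simulated Mann–Whitney p-values
  characterise the test, not the real-world effect;
* cohort class frequencies defaulting to the observed four-way study
  mix (43.6% euploid / 18.7% numerical / 28.0% imbalanced / 9.7% both),
  with whole-chromosome events drawn as full trisomies/monosomies and
  segmental events of 10–80 Mb (≤ 70% of a chromosome, terminally
  anchored half the time, like unbalanced translocation derivatives).

Passing the synthetic recovery tests therefore shows the estimator chain
is correct under this model — it does not certify performance on real
WGA libraries, whose bias is rougher than any smooth function of GC,
whose noise can exceed the default overdispersion, and which contain
mosaic signals the model excludes. All randomness derives from one seed
through fixed-index `SeedSequence` children, so any embryo is
reproducible in isolation and identical configurations give byte-wise
identical outputs.

## Problem sizes used in validation

The standing validation cohort is 50 embryos on the ~321 Mb genome at
study-scaled depth (events ≥ 10 Mb), on which the pipeline is required to
reach ≥ 95% four-way classification accuracy, ≥ 90% event recovery at
50% reciprocal overlap and ≤ 10% euploid false-call rate; segmentation
calibration uses 100 seeded pure-noise series of 100 bins, and oracle
equivalence uses noise-free step series of ≤ 30 bins against an exact
dynamic program.
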