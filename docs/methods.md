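# Methods

## Setting and assumptions

Four platforms profile the same cell lines: two sequencing-like platforms
reporting annotated read counts, one RT-qPCR-like platform reporting
quantification cycles (Cq), and one hybridization-like platform reporting
probe counts with six positive spike controls and eight negative controls
per sample. Measurements are per mature-miRNA target; platforms address
overlapping but unequal target panels under their own assay ids.

The analysis rests on three assumptions:

1. **A common canonical target space exists.** Assay ids map onto canonical
   mature miRNAs; targets a technology cannot distinguish are merged, and a
   platform is never scored on targets outside its panel.
2. **Per-miRNA capture bias is fixed within a platform.** Library
   preparation and probe chemistry distort each miRNA's measured abundance
   by a multiplicative factor that is the same in every sample, so the bias
   cancels in between-sample ratios. Absolute levels are therefore not
   comparable across platforms, but fold changes are.
3. **Presence can be defined by consensus.** Without synthetic spike-in
   ground truth, a data point counts as truly present when at least
   `min_platforms` (default 3) of the 4 platforms detect it.

## Pipeline

**Reference building.** Identical-sequence targets merge automatically;
assay-indistinguishable targets merge through explicit merge groups, with
overlapping groups unioned transitively (union-find). The canonical id of a
merged target is its lexicographically smallest member, making merging
deterministic and idempotent. When several assay rows map to one canonical
target, counts are summed and Cq takes the row minimum — preserving total
signal for count units and detection status for Cq. Unmapped assay ids are
returned as an explicit discard list, never silently dropped.

**Per-technology pre-processing.**

* Probe counts: per-sample spike factor = (mean spike-control sum over
  samples) / (this sample's spike sum), applied to targets *and* negative
  probes; then background subtraction at the negative-probe mean plus two
  sample standard deviations (n−1, appropriate at n = 8), floored at zero.
  The spike factor precedes background subtraction: the factor is a
  technical gain correction and must rescale the background estimate with
  the signal.
* Cq: linearized as `2^(cutoff − Cq)`, with missing or at/above-cutoff Cq
  mapping to 0. The cutoff (default 36, one PCR cycle ≈ one log2 unit) acts
  both as the detection boundary and the zero baseline; the back-conversion
  `cutoff − log2(x)` is its exact inverse below the cutoff.
* Read counts: none.

**Shared normalization.** Linear total-count scaling multiplies each sample
by `target_total / sample_total`; the default target is the arithmetic mean
of the platform's sample totals, which equalizes depth without changing the
platform's overall magnitude. Post-scaling totals agree to 1e−9 relative
tolerance; a zero-total sample is an error naming the sample.

**Detection and replicates.** Detection is decided per replicate on the
pre-scaling value: Cq below cutoff; background-corrected probe count > 0;
raw reads ≥ `min_reads` (default 1 — any annotated read counts as observed,
configurable). A target is detected in a cell line when a *strict majority*
of replicates detect it (2 of 2, 2 of 3), which is robust to single-replicate
dropout. The reported linear value is the mean over replicates with failing
replicates contributing 0; undetected targets report linear 0. Expression
percentile ranks are computed among detected targets only (average rank for
ties, scaled into (0, 1]).

**Statistics.** Consensus truth, sensitivity and specificity are defined on
the concordant panel (every platform targeted every scored miRNA). The
weighted pair score uses weight `p·(1+k)/(1+K)`; the corroboration factor
`(1+k)` and the percentile `p` implement the two monotonicity requirements
(more corroborated and more expressed points count more), and the constant
denominator cancels in the normalized score, so the score is determined by
the products `p·(1+k)` alone. Its ±1 endpoints are structural: identical
detection sets make every contribution +w, disjoint sets make every
contribution −w. The interior of the scale, however, depends on this
particular weight choice; any weighting satisfying the same monotonicity
and endpoint constraints is an equally valid construction, so interior
score values should be compared only within one implementation.

Fold changes require detection in both cell lines — dropouts are excluded
rather than floored, avoiding pseudo-count artifacts. A fold change of
exactly 0 is counted as agreeing with any sign (ties are not
contradictions). Pearson confidence intervals use the Fisher z transform.
Magnitude bins at 0.585/1.0/1.585 log2 units separate <1.5-fold, 1.5–2-fold,
2–3-fold and ≥3-fold changes; the binning variable is the mean |log2 FC|
across the participating platforms (the maximum is available by
configuration). Reported precision follows convention: percentages to
integers, weighted scores to 2 decimals, sensitivity to 3 decimals.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not any
particular instrument:

* **Baselines**: per-miRNA log2 abundance ~ Normal(μ₀ = 4, σ₀ = 4). The
  wide spread puts a realistic fraction of targets near each platform's
  detection limit, which is what makes platform sensitivities differ.
* **Effects**: exactly `round(de_fraction · n_mirna)` miRNAs (default 30%)
  are differentially expressed; each draws an independent per-line effect
  with random sign and magnitude uniform on `effect_range_log2` (default
  1–4 log2). The true log2 fold change between lines is the effect
  difference, independent of platform.
* **Biases**: per (miRNA, platform) log2 bias ~ Normal(0, 0.5), constant
  across cell lines — the library-preparation bias that cancels in fold
  changes but decorrelates absolute levels between platforms.
* **Panels**: by default the two sequencing-like platforms target the full
  reference and the qPCR-/hybridization-like panels are proportional
  subsets (722/1719 and 631/1719 of the reference) drawn so the
  all-platform intersection has a known size (517/1719), mirroring the
  scale of a real four-platform study design.
* **Measurement**: sequencing counts are Poisson at a given depth over
  relative abundances (negative binomial via gamma mixing when a dispersion
  parameter is set; exact expected counts in `sampling="expected"` mode);
  qPCR emits `Cq = c0 − log2(abundance) + N(0, σ)` censored at the cutoff;
  hybridization emits `efficiency · gain · abundance · bias` plus additive
  Gaussian background floored at 0, with spikes scaled by the per-sample
  efficiency and negatives carrying background only.

All randomness flows from one seed per call through per-stream derived
generators (a CRC of the stream label keys the spawn), so identical seeds
give bit-identical outputs.

What the generator does *not* emulate: read-level sequence artifacts,
isomiR length variants, cross-hybridization between near-identical
sequences, plate/batch effects, or biological replicate variation beyond
the per-platform noise models. Passing tests therefore demonstrate that the
statistics behave correctly under the stated stochastic structure, not that
any real platform attains a particular score.

## A note on total-count scaling with few targets

Scaling each sample to a common total introduces a per-(platform, cell-line)
log2 offset into every fold change: the offset is the log-ratio of the two
lines' panel totals, and it differs slightly between platforms because
panels and capture biases weight the totals differently. With the two-group
effect model (a fraction of miRNAs DE, the rest with *exactly zero* change)
this offset dominates the sign of null fold changes, making their sign
agreement unstable — a real property of total-count normalization on small
panels, not an artifact of the implementation. Real cell lines have no
exact-null miRNAs, so the experiments that mirror published figure designs
(percentile-resolved and magnitude-resolved agreement) run the generator
with `de_fraction = 1.0` and a continuous effect range (0.25–3 log2),
giving every miRNA a nonzero true change as between real cell lines.

## Fixed experiment designs used in the tests

* **Parameter recovery**: common full panels, zero bias, expected-mode
  sequencing counts, zero qPCR noise with an uncensorable baseline
  (μ₀ = 8, σ₀ = 2, c0 = 25), zero hybridization background; per-sample
  hybridization efficiency stays on (σ = 0.15) to exercise spike
  normalization. This configuration provably passes every statistic
  through unchanged: sensitivities 1.0, weighted scores 1.000, R = 1,
  100% agreement in every bin. With differing panels or nonzero bias the
  scaling offset above makes recovery approximate rather than exact, which
  is why the recovery scenario is bias-free.
* **Low-expression noise contrast**: 600 miRNAs, baseline Normal(4, 2),
  bias σ 0.3, sequencing depth 10⁷ (Poisson noise small at every
  expression level), qPCR cycle noise 0.25 (constant on the log2 scale),
  hybridization gain 20 over background Normal(100, 50) — an additive
  noise floor that swamps low-expressed targets only. Averaged over three
  seeds, pairs of the first three platforms stay flat across expression
  quintiles (within ±5 points of the pair mean) while every
  hybridization-containing pair loses >5 points in the bottom quintile and
  none in the top three — the mechanism by which an unamplified platform
  loses concordance specifically at low abundance.

Problem sizes in the test-suite simulations (60–600 miRNAs, 4 cell lines,
2–3 replicates) are scaled-down versions of the ~1719-target study design;
all statistics are size-free ratios, and the oracle-equivalence tests
(brute-force enumeration on ≤50-miRNA cubes) pin the counting logic
independently of scale.

## Known limitations

* The weighted pair score's interior values are construction-specific (see
  above); only its endpoints and orderings are comparable across
  implementations.
* Consensus truth is circular by design: a platform's sensitivity depends
  on the other platforms' detections. With `min_platforms = 3` of 4, one
  platform's total failure still leaves truth well-defined, but two
  correlated failures bias it.
* No statistical detection calling (FDR) and no inter-plate calibration
  beyond accepting pre-calibrated Cq; rejected normalization strategies
  (global mean, quantile, TMM) are out of scope.
* The qPCR simulator clips Cq at cycle 1 for physical plausibility;
  abundances high enough to hit the clip would distort recovered fold
  changes (not reachable under the default parameters).
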