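# Methods

This note documents the models, defaults and design choices behind
`circaphen`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Time conventions

All internal timestamps are elapsed decimal hours with recording start = 0.
The entrainment schedule defaults to 14 h light : 10 h dark, and because
recordings begin at lights-off, elapsed hour 0 is Zeitgeber Time 0 = dark
onset; hours [0, 10) of each day are dark. This is the lights-off ZT
convention; the more common lights-on convention is available via
`PhaseSchedule(zt0_is_dark_onset=False)`. Calendar parsing happens only in
the reader (`TableDialect.time_format`); everything downstream sees elapsed
hours.

## Binning

Raw channels are aggregated into uniform bins (default 0.5 h) tiling [0, T).
Rate channels (V̇O₂, V̇CO₂, RER) are averaged within bins; per-interval
increments (food, distance, activity counts) are summed. Empty bins are
missing (NaN), never zero, and are excluded from every mean — no imputation.
Each bin also records the mean timestamp of its contributing samples
(`bin_times`). Folding and phase labels use the bin start; regression uses
the mean sample time, which makes the cosinor acrophase unbiased whether a
bin holds a single sample at its left edge or dense samples across its width
(a half-bin phase bias, 15 min at 30-min bins, would otherwise appear in one
of the two cases). A bin is dark iff its start modulo the period falls inside
the dark span. Bins beyond the last complete day still contribute to diurnal
profiles by default (recordings are typically ~100 h, not an integer number
of days); `complete_periods_only=True` restricts folding to whole days. The
analysis window (e.g. to exclude habituation days) is an explicit
`[t_start, t_end]` option of the pipeline rather than a hard-coded rule.

## Cosinor model

Single-component cosinor at fixed period τ = 24 h (the animals are entrained;
period estimation is deliberately out of scope):

y(t) = M + β_c·cos(2πt/τ) + β_s·sin(2πt/τ), fit by ordinary least squares;
A = √(β_c² + β_s²), φ = (τ/2π)·atan2(β_s, β_c) mod τ, so the fitted curve is
M + A·cos(2π(t − φ)/τ). The acrophase is referenced to t = 0 = dark onset.

- **Log variant** (feeding, locomotion): fit after y ↦ ln(y + ε). Since those
  bins can be exactly zero, ε defaults to half the smallest positive observed
  bin value when zeros are present (else 0) and is recorded in the fit.
  Amplitude is reported in log units — the fit happened on that scale — with
  `fold_change = exp(A)` as the back-transformed peak/mesor ratio.
- **Degenerate fits**: for a constant series A ≈ 0 and φ is undefined; it is
  reported as 0 with a `degenerate` flag, and flagged fits must be excluded
  from group comparisons of acrophase.
- **Short records**: a span under one period yields a warning and an
  `unreliable` flag rather than a refusal; a design with all bins at one
  circadian phase is rank-deficient and errors.
- For gap-free sampling over whole periods the cosine/sine regressors are
  orthogonal to the intercept, so M equals the plain series mean;
  `mesor_equivalence_check` exposes this as a self-diagnostic (it
  legitimately fails when gaps break orthogonality).
- Group comparison of (M, A, φ) is per-animal + Mann–Whitney; a
  population-mean cosinor is not implemented.

## Sleep architecture

Sleep is scored behaviourally: a sleep bout is a maximal run of consecutive
zero-count activity epochs totalling at least `min_sleep_duration`. Defaults
are 10 s epochs and a 2 min threshold — cage systems of this type resolve
bouts of a few minutes, and 2 min is the conservative end of that range; both
are configurable, and a `merge_gap` option (default off) can bridge
single-epoch movement blips. Bout boundaries sit on epoch edges. Metrics over
an analysis window: per-phase sleep percentages use exact interval
intersections, so a bout spanning lights-on contributes to both phases
proportionally, while episode counts assign each bout once, to its starting
phase (counts stay integral). Wake episodes are the maximal complements of
sleep inside the window, so total sleep + total wake equals the window length
by construction. Sub-threshold inactivity is wake *by definition*; any
comparison against generative sleep fractions must therefore either filter
the ground-truth bout list at the same threshold or use a threshold small
relative to the generative mean bout length.

## Group statistics

- **ANCOVA** (body mass): response ~ group (categorical) + littermates
  (continuous). F statistics are Type-III style, from nested residual sums of
  squares: F_group = ((RSS_cov − RSS_full)/(k−1)) / (RSS_full/(n−k−1)), and
  analogously for the covariate. Model fits go through `statsmodels` OLS;
  the tests verify the F statistics against explicit normal-equation
  solutions. Adjusted means are the fitted group means at the grand covariate
  mean.
- **Fisher's LSD**: unadjusted pairwise t tests on adjusted means, with
  standard errors from the full-model residual mean square and the design's
  (XᵀX)⁻¹ geometry, df = n − k − 1. LSD follows the ANCOVA, so the contrasts
  are on covariate-adjusted (not raw) means. No multiplicity correction —
  that *is* the LSD convention — but `holm_adjust` is provided for users who
  want it. Under the null with normal errors the per-comparison level is
  exact; the acceptance script measures it by simulation (k = 3, n = 24,
  1000 replicates).
- **Mann–Whitney U** for everything else, two-sided. Auto mode is exact (full
  permutation distribution) when both groups have ≤ 8 observations and the
  pooled sample is tie-free, else the tie-corrected normal approximation with
  continuity correction — which is what the study-scale 7-vs-10 comparisons
  get. The computation is delegated to `scipy.stats.mannwhitneyu`; tests
  check the exact branch against full enumeration.
- **GTT AUC**: net trapezoid area of glucose minus the minute-0 baseline over
  the 0–120 min grid. Excursions below baseline subtract; "relative to
  baseline" is taken literally rather than clipping at zero.

## Histology quantification

Segmentation: a DAPI pixel is foreground when strictly above the mean of its
61 × 61 px neighbourhood (reflective padding; offset constant 0 by default,
configurable). The strict comparison carries a guard of 1e-9 × the intensity
scale because the sliding-sum mean of a constant image can differ from the
constant by a final-ulp error, which would otherwise binarize the whole
frame; a uniform image yields an empty mask. The mask is refined by five
iterations of binary opening with a 3 × 3 cross — the smallest standard
structuring element — then 8-connected components with area ≥ 50 px (at the
generator's scale; configurable) become nuclei. Touching nuclei are not
split: no watershed is applied, and counts are documented as connected
components. Per nucleus, the mark/DAPI ratio is mean mark intensity over the
segmented pixels divided by mean DAPI over the same pixels; this cancels any
common multiplicative illumination factor. Animals are summarised by pooling
nuclei across fields (mean ratio, n, SD) before group testing. Whole-nucleus
quantification only; focus-level analysis within nuclei is out of scope.
8- and 16-bit rasters are accepted; all arithmetic is in double precision.

## Synthetic-data generator

The generator is first-class, tested code, and its defaults are the study
conditions everything else is validated under: three groups of 7/10/10
animals, 96 h of recording sampled at 6 min (calorimetry) and 10 s
(activity), 30-min analysis bins, 14:10 LD starting dark.

- **Channels**: mesor + amplitude·cos(2π(t − acrophase)/24) + N(0, σ),
  clipped at 0 for physical channels (a small bias only when the mesor is
  within ~2σ of zero; documented, not corrected). Group parameter defaults
  echo the qualitative pattern the pipeline is meant to detect (raised V̇O₂
  amplitude and feeding in the 37 °C-culture group, intermediate 35 °C
  phenotype), at magnitudes chosen to be physiologically plausible for adult
  male mice (V̇O₂ ≈ 3 L/h/kg, RER between 0.8 and 1.0, feeding ≈ 0.15 g/h,
  locomotion tens of m/h).
- **Sleep**: alternating renewal with exponential bout durations, phase-
  dependent means (defaults: light 7 min sleep / 3 min wake → 70% sleep;
  dark 3/7 → 30%), discretized to whole epochs. Wake epochs emit
  Poisson(3) counts with the first epoch of each wake bout forced positive,
  so planted bouts are exactly the maximal zero runs up to rare chance
  zero-count wake epochs (P ≈ 0.05 per epoch; a ≥ 2 min spurious run needs
  twelve in a row, P ≈ 2·10⁻¹⁶). Exponential (memoryless) bouts are the
  simplest alternating-renewal choice; real rodent bout-length distributions
  are heavier-tailed, so recovery results here do not certify behaviour on
  power-law bout data.
- **GTT**: baseline + peak increment decaying exponentially from the 15-min
  sample (τ = 45 min default); a zero decay constant yields a sustained step,
  which reproduces the hand-computable 562.5 glucose·min case.
- **Mass**: linear model with group offsets and a negative littermate slope,
  with smaller litters in the IVF groups — so raw 3-week means are confounded
  by litter size exactly the way the covariate adjustment is meant to handle.
- **Images**: non-overlapping ellipses (semi-axes 7–11 px) with uniform
  per-nucleus DAPI level; inside nucleus i the noiseless mark equals
  ratio_i × DAPI, then both channels receive Gaussian noise (2% of dynamic
  range) and uint16 quantization. Placement is rejection sampling with a
  minimum separation; exhaustion raises with a hint to reduce the density.

Determinism: every generator stream is keyed by (design seed, CRC-32 of the
entity identifiers) through `numpy` `SeedSequence`, so outputs are
bit-identical across runs and independent across animals/fields, and any
single entity can be regenerated without generating the rest.

What the generator does **not** emulate — ultradian harmonics, weight-
dependent V̇O₂ scaling, non-exponential bout lengths, nucleus texture,
anisotropic illumination — bounds what passing tests show about real data:
they certify the estimators and their implementations under the stated
models, not robustness to every physiological artifact.

## Numerical choices

- Cosinor design matrices are solved by `numpy.linalg.lstsq`; rank is checked
  explicitly and amplitude below 1e-10 of the data scale marks a degenerate
  fit.
- Table round trips write floats at 17 significant digits and parse with
  correctly-rounded conversion, so synthetic-export round trips are
  bit-identical.
- RER alignment intersects exact timestamp values (both series come from the
  same instrument grid); points with V̇O₂ ≤ 0 are dropped with a warning.
- Negative feed/distance increments (hopper refills, balance resets) are
  clipped to 0 with a warning at ingest.
- Exact Mann–Whitney enumeration is capped at 8 per group (12 870 splits);
  beyond that the approximation's error is far below decision-relevant scales.

## Problem sizes

The test suite and acceptance script size their simulations to the study
scale or modestly above: 200 replicates for cosinor recovery, 50 random
designs for the ANCOVA oracle, all 70 + 252 label assignments for exact
Mann–Whitney, 1000 null replicates for LSD calibration, 1000 random traces
for the sleep oracle, and six 512 × 512 fields (72 nuclei) for segmentation
recovery. The full suite runs in well under a minute on one CPU.

## Known limitations

- No population-mean cosinor, multi-component harmonics, or period
  estimation.
- Sleep scoring is behavioural (immobility-defined); it cannot distinguish
  quiet wake from sleep, nor REM from NREM.
- ANCOVA assumes a common covariate slope across groups (no interaction
  term) and independent animals (no litter random effect).
- Touching nuclei are counted as one component; dense tissue would need a
  splitting step the source protocol does not describe.
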