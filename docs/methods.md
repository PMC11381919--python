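# Methods

## The synthetic recording model

Each well is a spontaneously beating monolayer on a rows × cols electrode
grid (default 4 × 4 at 300 µm pitch). The generator is phenomenological:
it renders the *waveform features the analysis measures*, not membrane
biophysics.

**Beat schedule.** Sinus cycle lengths are drawn from a truncated normal
with mean `mean_cycle_length` (default 1.0 s) and SD
`cycle_length_cov/100 × mean`, floored at `mean_fpd + 100 ms` so a full
FP complex always fits between beats. The 1.0 s default makes the
Fridericia correction the identity on average, so preset FPD values can
be read directly as FPD_c calibrations. With probability
`ectopic_probability` per sinus beat, an ectopic beat is interpolated at
a coupling interval of `ectopic_coupling_ratio × median CL`
(default 0.4) after it; the sinus schedule is not reset, so the ectopic
is followed by a relative pause — the classic tightly-coupled premature
beat followed by its compensatory interval.

**Wavefront.** Each beat activates the array as a plane travelling at
`wavefront_speed` along `wavefront_direction` (default: the array
diagonal, entering at one corner). Electrode activation time is the beat
time plus the projection of the electrode position onto the direction,
divided by speed. The preset speeds are derived from the target
wavefront crossing times over the diagonal projection span of the
default grid (1.27279 mm): 13 ms → 97.9 mm/s, 25 ms → 50.9 mm/s.

**Waveforms.** The depolarisation spike is a negative Gaussian
`−A·exp(−(t−t0)²/2s²)` with width `s = spike_width` (default 2 ms). Its
most negative derivative is `−A·e^{−1/2}/s` at `t0 − s`, so `A` is
solved analytically from `target_max_slope` and the spike is placed so
the maximum-downward-slope instant falls exactly at the activation time.
This makes the ground-truth slope exact by construction (the
`spike_amplitude` field is informational). The T-wave is a positive
Gaussian (default 0.1 mV, σ = 25 ms) whose *peak* sits exactly one true
FPD after the max-slope instant — the peak, not the onset, is the FPD
landmark. Per-electrode true FPD is
`mean_fpd + gradient·(projection − mean) + N(0, fpd_spatial_sd)`, drawn
once per electrode per well; the presets use gradient 0 so the
configured spatial SD is the dispersion ground truth. White Gaussian
noise (default 0.5 µV RMS, a low-noise post-filtering floor for modern
MEA amplifiers) is added last.

**Cohorts.** `N` differentiations × `n` wells per genotype. Each
differentiation draws an independent multiplicative offset
(mean 1, SD 5 %) for each of the five metric-bearing parameters,
emulating batch effects and making the random intercept identifiable.
Well seeds derive deterministically from (cohort seed, differentiation,
well), so any subset of a cohort is reproducible in isolation.

**What the generator does not emulate:** curved or re-entrant
wavefronts, conduction block, drifting baselines, electrode dropout or
impedance heterogeneity, beat-to-beat waveform variability (slope and
FPD are constant per electrode within a well), 1/f or line noise, and
rate-dependent FPD adaptation. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to every artefact of real recordings.

## Feature extraction

**Spike detection** thresholds the negative deviation from the trace
median at `8 × MAD`, with a floor of 25 % of the largest negative
excursion (which keeps the noise-free case, where the MAD is
numerically zero, well defined), a 200 ms refractory spacing, and
`scipy.signal.find_peaks`. Flat or silent channels yield no events, not
errors; sampling below 1 kHz is rejected as unsupported.

**Slope** is the minimum of a Savitzky–Golay first derivative
(quadratic, 0.6 ms window; plain central differences when the window
spans fewer than 5 samples) in a ±8 ms window around the spike trough;
ties break to the earliest sample. The short smoothing window matters:
differentiating raw white noise multiplies its SD by `√2·fs`, and taking
a *minimum* over a window then inflates |slope| by extreme-value
statistics — a bias that does not average out across beats or wells. At
the default noise floor the filter keeps that bias to ~1–3 % while
attenuating the clean template peak by < 0.7 % at 12.5 kHz (the
derivative filter is exact on linear ramps). This bias is the reason the
package does not claim unbiased slope recovery at arbitrary noise
levels: at noise ≥ 10 % of spike amplitude the extremum bias dominates
any averaging, a known limitation of min-of-derivative estimators.

**T-wave / FPD.** The T-wave is the maximum positive deflection from
baseline between `t_spike + 80 ms` and
`t_spike + 0.9 × (interval to the next spike on that electrode)`
(700 ms ceiling when unknown); a peak below 0.01 mV flags the beat
missing-T-wave (NaN FPD) rather than raising. `FPD = (t_twave −
t_spike)·1000`; `FPD_c = FPD / CL^{1/3}` with CL the *preceding*
well-level interval, so the first beat of a well carries no FPD_c.

**Well-level beats.** Because propagation spreads spike times by tens of
ms across the array, per-electrode events within a 100 ms window are
clustered into one well-level beat (time = median of member spike
times). A clustering window at or above the per-electrode median cycle
length is rejected as pathological.

**Ectopy.** A beat is classed ectopic when its preceding interval is
shorter than 0.6 × the running median of the previous ≤ 9 intervals
(trailing window, robust to rate drift); the first beat is always
regular. Ectopic beats stay in the feature table but are excluded from
slope/FPD/conduction/dispersion well summaries; they are *included* in
the COV, which is meant to capture total rhythm irregularity. With the
generator's 0.4 coupling ratio the classifier's recall is ~1; beats
immediately after an ectopic (interval ≈ 0.6 × CL) are sometimes also
flagged, which only makes the regular-beat summaries slightly more
conservative.

## Conduction and dispersion

*Maximum propagation* is max − min activation time per beat (≥ 3
electrodes required), averaged over regular beats per well — the
wavefront crossing time. Conduction velocity is the least-squares plane
`t = t0 + g·(x, y)` over electrode positions in mm; speed `1/|g|`,
direction `g/|g|`, with residual RMS reported. Collinear electrodes and
synchronous maps (|g| ≈ 0, unbounded speed) raise degenerate-geometry
errors rather than returning garbage. Dispersion is the sample SD
(n − 1 throughout the package) and range of per-electrode mean FPD over
regular beats; the per-electrode grid is exported row-major for spatial
maps.

## Nested inference

One row per well with five metrics: mean slope, mean FPD_c, COV %, mean
maximum propagation, FPD SD. Each metric is fitted (Gaussian, identity
link — the well-level metrics are all approximately normal) with a
random intercept per differentiation by REML (statsmodels `MixedLM`),
on a standardised response for numerical stability; estimates transform
back exactly. EMMs and their SEs come from the fixed effects; the
genotype contrast is a Wald z with a normal reference — no small-sample
df correction, so with few differentiations (N ≈ 6) the test is mildly
anti-conservative; the Monte-Carlo calibration at N = 20 per group
lands at ≈ 0.055 empirical type-I error for nominal 0.05. Degenerate
noise-free data (zero variance) short-circuits to exact group means
with a degeneracy flag (p reported 0 for a nonzero difference). Missing
wells are dropped listwise per metric. No multiplicity correction is
applied across the five MEA metrics.

Two oracle routes back the fit: a method-of-moments closed form for the
balanced two-level design (`fit_mixed_mom`; on balanced data REML and
the ANOVA estimators coincide, and the tests assert agreement to ~1e-6),
and an OLS route (`assume_zero_between_variance=True`) for the
zero-between-variance equivalence. The random-effects structure places
wells at the residual level (a single random intercept for
differentiation); with one observation per well a separate well-level
random term would not be identifiable.

## Expression

Counts are normalised by per-sample geometric means of housekeeping
genes (scale factor = cohort mean / sample factor; a zero housekeeping
count is an error naming the sample). log2 fold change is the difference
of group means of `log2(normalised + 0.5)` — the log ratio of
(pseudocounted) geometric means — and the per-gene test is Welch's
unequal-variance t on the same scale; genes constant in both groups get
p = 1. FDR control is the two-stage adaptive step-up: stage 1 at
`q' = q/(1+q)` estimates the null count `m̂₀ = m − r₁`, stage 2 reruns
the linear step-up at `q'·m/m̂₀`. Significance requires both the FDR
rejection at q = 0.05 and |FC| ≥ 2 in either direction.

The expression generator draws negative-binomial counts
(variance `µ + αµ²`) with a lognormal per-sample technical factor shared
by all genes, which is exactly what makes housekeeping normalisation
identifiable. Defaults — dispersion α = 0.01, base means 200–5000 —
emulate a high-count targeted hybridisation panel whose per-count CV
(~10–12 %) puts a 2.3-fold change well inside the detectable regime at
4 vs 4 samples; with strongly overdispersed biological replicates
(α ≥ 0.05) the same pipeline controls FDR but loses most of its
sensitivity at this sample size.

## Numerical choices and problem sizes

- Sample SD (ddof = 1) everywhere a spread is reported; COV uses it too.
- Argmin/argmax ties resolve to the earliest sample.
- CSV floats are written with 9 significant digits so re-runs diff
  byte-identically; JSON carries nested metadata; every CLI invocation
  writes a manifest listing its outputs and a config hash.
- All generators accept a single seed; cohort members use
  `SeedSequence`-derived child seeds, so results are independent of
  iteration order and subsets are reproducible.
- Default simulation: 12.5 kHz, 120 s. The test suite and the
  acceptance script run the cohort stages at 2 kHz and 10–120 s — sizes
  chosen so the whole suite completes in a few minutes while leaving
  every recovery tolerance intact; at 2 kHz the quantisation of the
  derivative costs ~2–3 % of |slope|, which the end-to-end tolerances
  absorb. Monte-Carlo sizes: 1000 replicates for the null calibration,
  500 p-vectors for the FDR oracle, 100 panels for the DE operating
  characteristics.
- End-to-end recovery is judged against the simulated cohort's own
  ground truth (the generator's truth tables averaged per genotype)
  rather than the raw preset constants: differentiation-level offsets
  are part of the data-generating process, and ectopy deliberately
  inflates the measured COV above the configured sinus COV.

## Known limitations

- The slope estimator's extremum bias under heavy noise (above).
- The Wald test has no small-sample correction; interpret p-values near
  0.05 cautiously when N is small.
- Housekeeping geometric-mean normalisation and the Welch test are
  documented substitutes for vendor-specific panel pipelines whose
  algorithms are not public.
- The plane fit assumes a single planar wavefront per beat; fractionated
  or re-entrant activation is out of scope.
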