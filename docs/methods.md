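# Methods

## The CGSD parameter system

A background-removed canopy photograph is an RGBA PNG whose transparent
pixels are background; statistics are computed over foreground pixels only
(alpha > 0 by default — cutouts produced by manual masking use hard
transparency). For each channel R, G, B and the gray level
Y = round(0.2989 R + 0.5870 G + 0.1140 B) (BT.601 weights,
half-away-from-zero rounding), the 256-bin histogram of foreground
intensities (the *gradation array*) yields five statistics: mean, median
(average of the two central order statistics for even n), mode (most
frequent level, ties broken toward the smallest level), skewness
m₃/m₂^{3/2} and kurtosis m₄/m₂² with population central moments.
Conventions are deliberately the MATLAB defaults of the parameter system's
origin: biased moments and non-excess kurtosis. At canopy-image pixel
counts (10⁴–10⁶) the bias-corrected variants differ negligibly, but fixing
the convention makes results exactly reproducible. A constant channel has
undefined skewness/kurtosis; these are flagged (NaN), never fabricated.

Two computational routes exist and are held equal by tests: per-pixel
summation and O(256) frequency-weighted formulas on the gradation array.

## Normality testing

Leaf gradation distributions are skewed; the package quantifies this with:

- **Jarque–Bera**: JB = n/6 (S² + (K−3)²/4) from the same biased moment
  pipeline as the CGSD parameters, p from the asymptotic χ²(2) tail
  (n ≥ 8 required).
- **Lilliefors**: D = sup |F̂ − Φ((x−x̄)/s)| with the unbiased sample SD.
  p-values come from a seeded Monte-Carlo null (default 10⁴ replicates;
  p = (1+exceedances)/(reps+1), valid and slightly conservative) rather
  than lookup tables, which end far below image-scale n. The statistic is
  location-scale invariant, so one null table per sample size serves any
  number of tests; helpers expose that amortization.

## Stepwise least squares, both directions

Selection follows the SPSS stepwise convention the field's published
tables imply: among excluded candidates compute each one's partial-F
p-value given the current model; enter the smallest if p < 0.05
(`p_enter`); after every entry remove any included predictor whose
partial-F p > 0.10 (`p_remove`); stop when nothing changes. Candidate
order — factors as (T_h, RH_h, AP_h, VP_h, TD_h), CGSD parameters in
(R, G, B, Y) × (Mean, Median, Mode, Skewness, Kurtosis) order — is the
deterministic tie-break. If no candidate ever enters, the result is the
explicit `unable_to_model` status: with weakly coupled data that is a
finding, not an error. A forced-entry mode fits all candidates without
selection. Final coefficients are ordinary least squares on the selected
set; an exactly collinear selected design raises an error naming the
predictors (selection itself sidesteps exact duplicates, whose partial F
is zero).

Reported fit statistics mirror an SPSS model summary: R², adjusted R²,
RMSE interpreted as the regression standard error √(SSE/(n−p−1)), the
overall F = (SSR/p)/(SSE/(n−p−1)) and its upper-tail p. Samples with
undefined moments are dropped per response (pairwise deletion).

Two statistical facts about this procedure are worth stating because tests
document them:

- Under a global null with five independent candidates, the probability
  that nothing enters is 0.95⁵ ≈ 77 %, not ~95 % — the entry test is a
  minimum over five p-values. The test suite asserts the true calibration.
- After the true predictors are in, each remaining null candidate still
  enters with ~5 % probability, so "selected set exactly equals the
  planted set" fails at the family-wise spurious-entry rate; recovery is
  therefore judged as "planted predictors selected", not set equality.

## Prediction accuracy and outliers

accuracy = (1 − |predicted − measured| / |measured|) × 100 %. The
denominator uses the magnitude because near-zero and negative measured
values (skewness!) make the signed form ambiguous; samples with
|measured| ≤ 1e-9 are reported as non-computable. A holdout sample with
accuracy < 0 % (relative error > 100 %) is an outlier by default
(configurable); the headline mean accuracy excludes outliers — otherwise a
single near-zero skewness sample dominates the mean — and the inclusive
mean is reported alongside. This reproduces the qualitative pattern that
channel-mean models validate at ≥ 95 % with no outliers while skewness
models generate many.

## Temperature regimes

2-means clustering on T_h uses the exact 1-D algorithm: sort, scan all
n − 1 contiguous splits, minimize within-cluster SS. Optimal 1-D 2-means
clusters are contiguous, so this is the global optimum — deterministic, no
initialization, provably no worse than any Lloyd run (tests compare
against 100 seeded Lloyd initializations per instance). The higher-mean
cluster is T1 ("normal temperature"), the lower T2; T0 denotes the
unsplit set for per-regime re-modeling. Ties in the scan go to the
smallest split index.

## The synthetic study generator

The generator defines the package's reference study conditions; it is
tested code, not a fixture.

**Weather.** T_h = mean + A·sin(2π(h−9)/24) (peak 15:00) − cold-wave
deficit + N(0, σ_T); RH_h = base + slope·(T−mean) + noise, clipped to
[5, 100] (anti-coupling, slope < 0); TD_h from (T, RH) by Magnus inversion
(β = 17.62, λ = 243.12 °C); VP_h = 6.112·exp(βTD/(λ+TD)); AP_h = base +
slow sinusoidal drift + noise. Derived TD/VP guarantee the physical
invariants (TD ≤ T, VP > 0) by construction. Cold waves subtract their
full depth on the days they cover. The Magnus helpers exist for the
generator only; observed CSV columns are never recomputed.

**Images.** Foreground is a centered ellipse (~10⁴ pixels at the default
128×128 size). Each channel's pixels are drawn from 255·Beta(α, β) with
mean = planted location = a_c + Σ_f b_{c,f}·f(record) and concentration
α+β fixed per channel (default 25), plus N(0, 2) pixel noise, clipped and
rounded to 0–255. Bounded support matches 8-bit gradation and location
below mid-scale yields the right-skewed histograms real leaf images show.
A location leaving (0, 255) raises an error naming the factor values
rather than silently saturating. `concentration = inf` degenerates to a
point mass (useful for exactness tests). All randomness flows from one
scenario seed through named substreams (weather; one per image).

**Reference scenarios**, fixed once as the study conditions:

- *greenhouse* — 7 days × hours (7, 9, 12, 15, 18), T 26 ± 6 °C, RH ~70 %
  anti-coupled, AP ~1005 hPa stable; planted maps
  R: 30 + 1.2·VP_h, G: 60 + 0.35·RH_h + 0.8·VP_h, B: 55 (flat — so B-mean
  models are correctly `unable_to_model`).
- *cold wave* — 12 days × hours (8, 9, 10, 16) around 6 °C with a 7 °C
  wave on days 5–7, producing the bimodal T_h marginal the regime
  classifier must split inside the gap.

**What the generator does not emulate**: leaf geometry and occlusion,
illumination drift, white-balance artifacts, frost/snow frames,
inter-channel pixel correlation, spatial texture. Passing tests therefore
demonstrate the *statistical machinery* — extraction exactness, selection
behavior, calibration, recovery of planted linear structure through the
full image path — not photorealism or biological validity on real crops.

## Identifiability caveat

Dew point and vapor pressure are deterministically linked by the Magnus
bijection and near-linearly related over any realistic hourly range
(r ≈ 0.999 in generated series). They are statistically interchangeable
predictors: stepwise may express a planted VP signal in the TD basis with
the slope scaled by dVP/dTD (~1.5 hPa/°C at 20 °C), or fold a
moisture+temperature signal into (T, TD). Recovery checks therefore judge
selection up to this moisture equivalence, and coefficient coverage is
evaluated in the planted (RH_h, VP_h) parameterization via residual
bootstrap (centered, leverage-corrected residuals on the fixed design;
percentile intervals; 1000 replicates) — the appropriate scheme for the
generator's fixed-design, homoskedastic error structure, and the best
calibrated of the flavors evaluated on held-out seeds.

## Numerical and scale choices

- Image/record pairing: nearest record within 30 min, equidistant ties to
  the earlier record; unpaired images are listed, never dropped.
- Pearson p-values: two-tailed t, n − 2 df; constant columns flagged NaN.
- Monte-Carlo sizes in tests are scaled to keep the default suite fast
  (e.g. 2000-replicate Lilliefors null reused across 200 calibration
  samples; 50-seed end-to-end recovery at 35 images × ~10⁴ pixels);
  the acceptance script uses a 500-replicate null at image-scale n.
- Cumulative curves force the final value to exactly 1 to cancel float
  accumulation error.
- Dew-point inversion is valid for RH ∈ (0, 100]; vapor pressure for
  TD ∈ [−60, 60] °C.

## Known limitations

- Only k = 2 temperature regimes; multivariate regime classification is
  out of scope.
- The stepwise procedure inherits the SPSS thresholds' multiplicity
  behavior described above; no correction is applied across the 100
  correlation cells, matching field practice.
- Accuracy percentages are undefined for measured values at zero; such
  samples are surfaced, not imputed.
- Observed meteorology is taken as-is; no quality control beyond the
  validation bounds (RH ∈ [0,100], VP > 0, plausibility warnings for AP
  and TD > T).
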