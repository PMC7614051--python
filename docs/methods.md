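# Methods

## Retrieval model

The package retrieves winter-wheat LAI from multi-orbit Sentinel-1 VH/VV
γ⁰ time series in three steps: (1) per-pixel, per-band Whittaker
smoothing/interpolation onto a daily grid with automatic selection of the
smoothing parameter; (2) Gaussian process regression (GPR) from the
6-band feature vector (VH, VV per track, in dB) to LAI, with a posterior
SD per estimate; (3) application of the fitted model to feature cubes for
seasonal LAI / LAI-SD mapping, per-paddock aggregation, and distribution
fitting. Backscatter stays in dB end to end: smoothing, regression and
mapping all operate on dB values, which is standard practice for S1
γ⁰ analysis and keeps the feature space roughly Gaussian.

### Whittaker smoother

The objective λ Σ ωⱼ(yⱼ−xⱼ)² + Σ (Δᵖxⱼ)² is used with λ on the fidelity
term. This is deliberate: it matches the convention of the equations the
implementation follows, and the bijection λ_penalty = 1/λ recovers the
more common penalty-side form. Consequences worth remembering: λ → ∞
reproduces the data, λ → 0⁺ tends to the weighted polynomial fit of
degree p − 1, and "smoother" means *smaller* λ. With p = 2 and uniform
weights the smoother preserves the first two sample moments (Σx̂ = Σy,
Σj·x̂ⱼ = Σj·yⱼ), which the tests assert to 1e−8.

The weighted normal equations (λW + MᵀM)x̂ = λWy are solved with a
symmetric banded factorization (`scipy.linalg.solveh_banded`); bandwidth
equals p, so the solve is O(n·p²). Interpolation sets ω = 1 on observed
days and ω = 0 elsewhere, requiring at least p + 1 observed samples.

λ selection: default is the V-curve on a log₁₀ grid of [−4, 4] with step
0.1 (spanning several orders of magnitude on both sides of 1); the
selected λ is the log-midpoint of the adjacent grid pair whose (ψ, φ)
points lie closest, ties broken toward the smaller (smoother) λ. If the
curve degenerates (non-finite coordinates, e.g. exact zero residual
everywhere), selection falls back to the fidelity-dominant (largest-λ)
grid end and records a warning. GCV is available as an alternative; its
effective hat matrix is H = λ(λW + MᵀM)⁻¹W, which reduces to the
classical λA⁻¹ for uniform weights, and the score denominator
1 − tr(H)/n must stay positive. One λ is selected per (pixel, band,
track) series. Because all pixels of a track share one acquisition
calendar, the factorization at each grid λ is shared across pixels and
the criterion is evaluated vectorized; ESU feature extraction runs the
same code path restricted to the ESU pixels, so point features and map
cubes agree to machine precision by construction.

A practical note from the tests: the truth-RMSE of the smoothed series is
very flat around its optimal λ, so the V-curve choice lands within two
grid steps of the brute-force optimum reliably only on a 0.25-dex grid
(≥ 80 % of replicates), while its *attained* RMSE stays within a few
percent of the optimum on any grid.

### Gaussian process regression

ARD squared-exponential kernel with θ = [v, σ_n, σ₁…σ_B]; the bias α₀ is
a constant prior mean fixed at the training-label mean (no fitting rule
beyond that is needed; far from the data, predictions revert to α₀ and
the SD to √(v + σ_n²)). Features are centered/scaled by training
statistics before entering the kernel — ARD length scales are otherwise
unit-dependent — and the transform is stored in the model.

Hyperparameters maximize the log marginal likelihood with analytic
gradients (L-BFGS-B in log-parameter space, bounds ±10 nats) from a
moment-based initial guess (v = var(y), σ_n = 0.1·sd(y), σ_b = 1 on
standardized features) plus seeded log-normal perturbations; 5 restarts
by default, deterministic given the seed. Numerically indefinite trials
are rejected with an infinite objective; only the final factorization of
the selected model may receive escalating relative jitter
(1e−10 → 1e−6, logged). The predictive variance is the standard GP
posterior variance under this kernel, floored at 0; predicted LAI means
below 0 are clipped to 0 in maps with a logged count. A constant
training target yields a flagged degenerate model (constant predictions,
meaningless relevance ranking). Models serialize to a self-describing
JSON container so train/map can be separate processes.

### Validation

Metrics are computed exactly as defined (R², MAE, RMSE, NRMSE in percent
of the label range). k-fold CV (k = 10) partitions samples by a seeded
permutation into near-equal folds (the first N mod k folds take one
extra sample); out-of-fold predictions are pooled into a single report —
pooling is the aggregation consistent with plotting one measured-vs-
estimated scatter — and per-fold reports are retained. Hold-out
validation uses a seeded shuffle with train size floor(N·fraction),
default 0.7. The scenario matrix has 9 rows: {S1A-141, S1A-68, S1B-68,
merged 6-band} × {raw, smoothed} hold-out rows plus the merged-smoothed
CV row. The elapsed-time column is informational only and never tested
(hardware-dependent). Raw-scenario features pair each sampling date with
the nearest acquisition per track (ties to the earlier date; Δ-day
summaries rounded half-up); smoothed-scenario features are taken from the
interpolated series at the field date itself, which is the point of
interpolating in the first place.

## Synthetic scene generator

The generator emulates the study conditions the retrieval assumes, so the
pipeline is testable without external data:

- **Geometry**: a 60×60 grid of 10 m pixels (UTM-like coordinates), three
  axis-aligned rectangular paddocks, 12 bare-soil samples outside them.
- **Tracks**: S1A-141 (12-day cadence, mean local incidence angle 33°),
  S1A-68 and S1B-68 (12-day each, interleaved to a 6-day cadence on
  orbit 68, mean LIA 43°, one shared LIA raster per orbit); LIA fields
  are Gaussian with 0.5° spatial SD. Season window 27 Aug 2020 –
  12 Jan 2021; acquisition time-of-day is ignored.
- **Phenology**: double-logistic LAI curve (product of rising and falling
  logistics, rising inflection one third of the way from emergence to
  senescence onset), scaled to a 4.1 m² m⁻² seasonal peak, zero before
  emergence (day 5) and from harvest (day 130) on. Defaults (growth rate
  0.085 d⁻¹, senescence onset day 88, rate 0.12 d⁻¹) track the reported
  field course: ≈0.5 in early September, ≈2.6 in early October, ≈4.1 at
  the start of November. Per-pixel peak values vary log-normally
  (SD 0.10); the analytic argmax is exposed for truth comparisons.
- **Forward model**: water-cloud-style two-term γ⁰ in linear power,
  A·cosθ(1 − e^(−2B·LAI/cosθ)) + cos²θ·S(mv)·e^(−2B·LAI/cosθ) with soil
  level S(mv) = 10^((C + D·mv)/10). Defaults (VH: A 0.12, B 0.35,
  C −24 dB, D 15 dB; VV: A 0.25, B 0.25, C −17 dB, D 18 dB) give the
  qualitative behavior the retrieval exploits: γ⁰ rises with LAI and
  saturates, falls with incidence angle, and brightens with soil
  moisture; monotonicity in LAI holds whenever A ≥ cosθ·S(mv), true for
  volumetric moisture up to ≈0.45.
- **Soil moisture**: a 0.08 base plus exponential-decay pulses
  (amplitude 0.2, 10-day decay) at days 1, 20 and 90, mirroring the
  three gravity irrigations of the campaign.
- **Speckle**: multiplicative unit-mean gamma noise in linear power with
  shape = ENL, default 10, mimicking imagery after adaptive and 3×3 mean
  filtering.
- **In situ sampling**: 9 ESUs (3 per paddock, pixel centers), five
  sampling dates inside the green-up window (3 Sep – 2 Nov), each label
  the mean of 6 replicate readings with 0.5 m² m⁻² replicate noise
  (so ESU-mean noise ≈ 0.20 m² m⁻²), clipped at 0; plus 12 non-vegetated
  zero-LAI samples — 57 samples in total.

Every stochastic output is a pure function of (config, seed) via spawned
`SeedSequence` streams.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no orbital geometry or radiometric terrain
effects (the emulated site is flat), no spatially correlated speckle or
soil-moisture heterogeneity, no crop-row-orientation or dew/diurnal
effects, no senescence-stage divergence between green and total LAI (the
forward model is driven by a single LAI), and rectangular paddocks only.
Real-data performance figures cannot be inferred from the synthetic
scores; only the method's internal consistency and qualitative behavior
(smoothing helps; merged multi-angle features help; uncertainty is
calibrated against the generative noise) carry over.

## Problem sizes and runtimes

Default experiments use 60×60-pixel scenes (≈1 500 cropland pixels),
57 training samples, and 25 scene replicates for the scenario-ordering
experiment; the full test suite runs in about four minutes on one CPU,
the acceptance script in well under one. These sizes were chosen so the
statistics of interest (scenario ordering, recovery errors) are stable
while experiments remain quick to iterate.

## Known limitations

- The V-curve selection rule needs at least a 3-point λ grid; a 2-point
  grid is rejected rather than treated as a single-interval special case.
- GCV's trace term is computed with a dense identity solve, O(n²·p) per
  grid λ; fine for daily series of a season's length, wasteful for much
  longer grids.
- Per-paddock uncertainty is the mean of per-pixel SDs; variance
  propagation across correlated pixels is out of scope.
- Weibull fits exclude non-positive values (with a logged count) rather
  than modeling zero inflation.
- Raster I/O is deliberately minimal: single-band north-up ASCII grids
  with square pixels; CRS metadata travels in manifests, not in the
  raster files.
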