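# Methods

## The sensing model

A fluorescent molecularly imprinted nanoparticle (nanoMIP) carries organic
fluorophores in two environments: randomly placed on the polymer backbone
and located in or near the template-shaped binding cavities. The measured
TCSPC decay is modelled as a biexponential,

I(t) = A + B₁·e^(−t/τ₁) + B₂·e^(−t/τ₂),

where τ₁ (fast) is a global descriptor of the non-specific population and
τ₂ (slow) responds to template binding. Binding of the analyte quenches the
cavity-proximal reporters and *shortens* τ₂; plotted against analyte
concentration x, τ₂ traces a decreasing binding isotherm.

### Isotherm forms

* Lifetime readout — baseline Hill:
  τ₂(x) = τ₂₀ + (τ₂_max − τ₂₀) · xⁿ/(EC50ⁿ + xⁿ).
  The zero-baseline variant τ₂_max·xⁿ/(K + xⁿ) predicts τ₂(0) = 0, which is
  inconsistent with a finite blank lifetime; it is kept only as a
  documented reference (`predict_hill_bare`). With n ≠ 1 the mass-action K
  carries units Mⁿ, so the fit is parameterized by EC50 in molar units
  (EC50ⁿ = K): the half-saturation concentration — the apparent
  dissociation constant K_app — is the directly fitted quantity.
* Intensity readout — Langmuir: y(x) = START + (END − START)·x/(k + x),
  the n = 1 special case.

### Figures of merit

From a converged Hill fit and the blank scatter:
K_aff = 1/K_app; sensitivity at low concentration S = |τ₂_max − τ₂₀|/K_app
(defined at the fitted parameters — the derivative of the Hill curve at
x = 0 vanishes for n > 1 and would be useless); LOD = 3·σ_blank/S; linear
dynamic range x_f = EC50·(f/(1−f))^(1/n) at f = 0.10 and 0.90, whose
endpoints bracket EC50 with geometric mean exactly EC50. σ_blank is always
an explicit input (≥2 replicate blank τ₂ values or a supplied override),
never a hidden constant, so an LOD can never rest silently on a single
blank measurement.

## Forward model and simulation

Time axis: channel i covers [i·w, (i+1)·w) with w = 109.73 ps by default;
models are evaluated at channel centers; 1023 channels span ≈ 112 ns.

The prompt (IRF) is a discretized Gaussian — channel weights are exact CDF
differences — with default FWHM 500 ps centred at 2 ns. A real
photon-counting prompt's shape is instrument-specific; a Gaussian of
comparable width is the standard stand-in and every fitting routine accepts
any measured prompt histogram in its place.

Expected counts are the discrete linear convolution of the unit-sum prompt
with the decay law, truncated to the window, plus the constant background
A. The expectation is rescaled so its modal channel equals the peak target
(10,000 counts) *before* Poisson sampling: the observed peak then
fluctuates around the target, mimicking stop-at-peak acquisition without
modelling acquisition order. Observed counts are channel-wise Poisson.

Generator defaults are the study conditions: τ₂₀ = 4.183 ns,
τ₂_max = 3.983 ns, EC50 = 18 pM, n = 1.89 for the lifetime isotherm;
I₀ = 34,399 rfu, I_min = 23,103 rfu, EC50 = 30 pM for the intensity
isotherm; concentration grids log-spaced over 100 fM – 150 nM (10 points,
triplicate); aggregated-response noise Gaussian with sd 0.009 ns (τ₂) or
500 rfu (intensity), matching the reported parameter uncertainties. The
fast component is rarely reported in characterizations of this sensor
class; the generator defaults to τ₁ = 1.0 ns with B₁ = B₂ and both are configurable —
the recovery results are insensitive to this choice as long as τ₁ and τ₂
are well separated. Decay-level simulations default to a dark-count
background of 10 counts/channel; goodness-of-fit calibration studies use
50 counts/channel (see "Objective and χ²" below).

Seeding: one seed per run; per-concentration and per-stage child streams
are spawned deterministically (`numpy` SeedSequence), so identical
configurations reproduce every output byte for byte and no two stages share
RNG state.

## Reconvolution fitting

Objective: Neyman-weighted least squares Σ (obs − exp)²/max(obs, 1) — the
χ² convention of standard TCSPC analysis software — minimized by
Levenberg–Marquardt (lmfit) with analytic-free numerical derivatives. A
Poisson maximum-likelihood objective (C-statistic) is available via
`objective="poisson"` but is not the default. A single sub-channel prompt
shift (linear interpolation, bounded ±5 channels) is a free parameter:
reconvolution without a shift is brittle against sampling-phase mismatch.

Bounds: lifetimes ∈ [w/10, 10 × window]; amplitudes and background ≥ 0.
Labels: τ₁ ≤ τ₂ always, enforced by swapping lifetimes together with their
amplitudes after the fit (the sum of exponentials is symmetric, so the swap
never changes the objective). Collapse of the biexponential onto one
component (amplitude fraction < 1% or τ₁ ≈ τ₂) is reported as a warning on
the result, not an error. Non-convergence is a reported state
(`converged=False`) with diagnostics; such fits are excluded from isotherm
input.

Initial guesses are data-driven: background from the pre-rise baseline
channels (or the floor of trailing block means when the decay starts at
channel 0), lifetime from a log-linear regression on the last 30% of
above-background tail channels, amplitudes from the peak height.

Numerical details: the optimizer runs at tight tolerances (xtol = ftol =
1e-12, ≤20,000 evaluations); if it converges without recoverable error
bars (a finite-difference step can collapse when a parameter lands at ~0)
one pass at standard tolerance is retried from the initial guesses. A fit
with near-zero residuals (reduced χ² < 0.05, noise-free data) is accepted
as converged even though error bars are undefined there.

### Objective and χ²

Reduced χ² = Σ (obs−exp)²/max(obs,1) / (N − p) over all channels (no
low-count exclusion by default). Neyman weights are biased upward for
channels with fewer than a few tens of counts — E[(X−μ)²/X] ≈ 1.31 at
μ = 10 — so a correctly specified model yields reduced χ² ≈ 1 only when
most channels sit above that regime. The goodness-of-fit calibration
studies in the test suite therefore simulate a 50 counts/channel dark
background, for which the statistic is calibrated (mean ≈ 1.02, 95% of
seeds within [0.8, 1.2] at 1023 channels); at a 10 counts/channel
background the same statistic centres near 1.13 by construction, without
any model misfit. Parameter estimates are affected only marginally
(τ₂ bias ≈ 0.1% at 10 counts/channel, < 0.05% at 50).

### Verification oracle

`grid_oracle_fit` minimizes the same objective by exhaustive search over a
lifetime grid, solving amplitudes and background in closed form by
nonnegative linear least squares at each node. It exists to bound the
optimizer in tests (the continuous fit must never do worse than the grid
minimum plus resolution slack) and is never used in analysis.

## Isotherm fitting

Fits run on log₁₀-concentration for conditioning; EC50 standard errors are
delta-transformed back to linear units. The Hill coefficient is bounded to
[0.2, 6]. Deterministic multi-start (EC50 initialized at the quartiles of
the log-concentration range, n at 1 and 2) guards against the occasional
false ftol stop of a single Levenberg–Marquardt start on plateau-shaped
objectives; the lowest-SSR result wins.

Weights: inverse-variance on the group means with the per-point variances
moderated to the pooled replicate variance. Raw per-point variances from
triplicates are themselves ~70%-noisy and weighting by them degrades the
stderr calibration badly (±2·stderr coverage of EC50 drops to ~0.82 in
simulation); pooling restores nominal coverage (~0.89–0.95) while remaining
inverse-variance in expectation. Noise-free data (zero dispersion) and
single-replicate points fall back to unweighted.

Flat titrations — response span below twice the pooled replicate noise —
are reported `converged=False` without fitting, mirroring sensors that do
not respond; `assemble_metrics` refuses non-converged fits. Non-monotone
series beyond 3× noise proceed with a warning.

## Selectivity and matrix workflows

Panels fit every replicate decay biexponentially with τ₁ fixed from the
blank condition, average τ₂ per condition and compare against the blank.
Calls use 3× the pooled within-condition replicate sd (consistent with the
3σ LOD convention): drop beyond it → binder; |change| within it →
non-binder; a significant *increase* → indeterminate, since lifetime
increments signal non-specific adsorption rather than cavity binding.
Conditions with fewer than two converged replicate fits are indeterminate;
if the blank itself cannot be fit the whole panel degrades to indeterminate
with the reason recorded.

The spiked-matrix assay follows the measurement protocol in which the
unspiked matrix sample (matrix + nanosensors, no spike) serves both as the
reference condition and as the deconvolution prompt. Using a fluorescing
sample as the prompt is deliberately unconventional — deconvolving a
*faster* decay against a *slower* prompt is ill-posed under nonnegative
amplitudes, and on synthetic data the component fits are degenerate, so the
protocol-faithful default typically returns indeterminate calls with
diagnostics. Supplying a true instrument prompt (`instrument_prompt=`)
yields quantitative calls; both paths record which histogram served as
prompt.

## What the synthetic data do and do not show

The generator reproduces the *statistical* structure of the acquisition:
Poisson channel noise, peak normalization, IRF convolution, isotherm-driven
τ₂, replicate scatter. It does not model detector afterpulsing, pile-up,
dead time, wavelength-resolved emission, matrix photophysics
(autofluorescence, inner-filter effects) or drift. Passing tests therefore
demonstrate that the estimators are correct and calibrated for the stated
noise model at the stated scales — not that any particular real instrument
is free of the unmodelled effects.

## Problem sizes

Test-suite simulations use the full 1023-channel instrument for
calibration claims (100 Poisson replicates for bias/coverage, 40–100 seeds
for χ² banding) and a 128–256-channel miniature instrument for property
tests and oracles. `scripts/acceptance.py` uses 50 seeds per quantity at
the full instrument scale.

## Known limitations and open points

* The mass-action K printed alongside published sensor characterizations
  of this type is sometimes the reciprocal of a concentration other than
  the fitted EC50; this package always reports K_aff = 1/K_app exactly.
* The low-concentration sensitivity is a secant (span over EC50), not a
  slope; alternative definitions (IUPAC calibration-curve slope) are out of
  scope.
* No global multi-dataset fitting beyond the fixed-τ₁ convention; no
  phasor analysis; no lifetime-distribution (maximum entropy) methods.
* Uncertainty propagation into LOD and dynamic range is not performed
  beyond carrying the fit standard errors.
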