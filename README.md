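# tausense

Fluorescence-lifetime analysis for optical nanosensors read out by
time-correlated single-photon counting (TCSPC).

Molecularly imprinted polymer nanoparticles (nanoMIPs) carrying a
fluorescent reporter respond to binding of their template protein — here
serum albumin at femto- to nanomolar levels — with a measurable *decrease
of the fluorescence lifetime* of the reporters sitting in or near the
imprinted binding cavities. `tausense` implements the full desk side of
that sensing scheme:

* **Synthetic TCSPC data** with the acquisition statistics of a
  photon-counting spectrometer: 1023 channels at 109.73 ps/channel, decays
  normalized to ~10,000 counts in the peak channel, Poisson counting noise,
  and a Gaussian prompt (instrument response function, IRF).
* **Iterative reconvolution fitting** of decay histograms with
  mono- and biexponential models,

  I(t) = A + I₀·e^(−t/τ)  and  I(t) = A + B₁·e^(−t/τ₁) + B₂·e^(−t/τ₂),

  convolved with the measured prompt; Neyman-weighted least squares
  (Σ (obs−exp)²/max(obs,1)), per-parameter standard errors, reduced χ²,
  sub-channel IRF shift, and the fixed-τ₁ convention for titrations (τ₁
  describes the non-specific reporter population; τ₂ is the
  binding-responsive component).
* **Binding isotherms** across an analyte titration: the Langmuir model
  y = START + (END−START)·x/(k+x) for intensity readout and the
  baseline-Hill model τ₂(x) = τ₂₀ + (τ₂_max−τ₂₀)·xⁿ/(EC50ⁿ+xⁿ) for
  lifetime readout, with EC50 ≡ K_app the apparent dissociation constant.
* **Sensor figures of merit**: K_aff = 1/K_app, sensitivity
  |τ₂_max−τ₂₀|/K_app, limit of detection LOD = 3·σ_blank/sensitivity, and
  the 10–90% linear dynamic range x_f = EC50·(f/(1−f))^(1/n).
* **Comparative workflows**: selectivity panels against non-template
  proteins and spiked-matrix (wine) assays with matrix-matched prompts,
  with 3σ binder / non-binder / indeterminate calls.

The package is aimed at spectroscopists and sensor developers who want a
reproducible, scriptable alternative to vendor decay-analysis software for
lifetime-based binding assays.

## Worked example

```python
import tausense as ts

config = ts.InstrumentConfig(seed=42)          # 1023 ch × 109.73 ps, peak 10,000
irf = ts.make_irf(config)                      # Gaussian prompt, FWHM 500 ps

truth = ts.DecayModelParams(kind="bi", a=10.0, b1=1.0, tau1=1.0, b2=1.0, tau2=4.183)
decay = ts.simulate_decay(truth, irf, config)  # Poisson photon counts
fit = ts.fit_biexponential(decay, irf, fixed_tau1=1.0)
print(fit.params.tau2, fit.stderr["tau2"], fit.chi2_red)
```

prints (seed 42)

```
fitted tau2 = 4.1864 ± 0.0135 ns (truth 4.183 ns)
reduced chi2 = 1.083  converged = True
```

— the binding-site lifetime is recovered within one standard error and the
reduced χ² ≈ 1 confirms the Poisson noise model. Building the titration and
the figures of merit (`examples/02` and `examples/03`):

```
EC50 = 19.1 ± 1.4 pM   n = 1.87   adj. R2 = 0.9965
K_app_pM            18        LOD_pM          0.81
K_aff_per_M         5.556e+10  LDR             5.63 – 57.6 pM
sensitivity_ns_per_M 1.111e+10
```

K_app is the analyte concentration at half response; the LOD converts three
blank standard deviations (here 0.003 ns) into concentration units.

The `examples/` directory holds one short narrative script per capability;
each builds its own input, runs the method and prints what the numbers
mean. A thin CLI mirrors the pipeline stages:

```bash
tausense run --seed 11 --out run_dir          # end-to-end
tausense simulate --seed 1 --out data/        # prompt + decay titration
tausense fit-decays data/ --prompt data/prompt.txt --fixed-tau1 1.0
tausense fit-isotherm titration.tsv --model hill
tausense metrics isotherm_fit.json --blank-sd 0.003
```

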