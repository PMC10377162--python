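"""Simulate one photon-counting decay and recover its lifetimes by
iterative reconvolution.

Builds the reference instrument (1023 channels, 109.73 ps/channel, Gaussian
prompt with 500 ps FWHM), simulates a biexponential decay with Poisson
noise, and fits it with the fast component fixed.
"""

import tausense as ts

config = ts.InstrumentConfig(seed=42)
irf = ts.make_irf(config)

truth = ts.DecayModelParams(kind="bi", a=10.0, b1=1.0, tau1=1.0, b2=1.0, tau2=4.183)
decay = ts.simulate_decay(truth, irf, config)
print(f"simulated decay: {decay.n_channels} channels, "
      f"peak {decay.counts.max()} counts (target {config.peak_target})")

fit = ts.fit_biexponential(decay, irf, fixed_tau1=1.0)
print(f"fitted tau2 = {fit.params.tau2:.4f} ± {fit.stderr['tau2']:.4f} ns "
      f"(truth 4.183 ns)")
print(f"reduced chi2 = {fit.chi2_red:.3f}  converged = {fit.converged}")
# tau2 is the binding-site lifetime; ~1 for reduced chi2 means the Poisson
# noise model fully explains the residuals.
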