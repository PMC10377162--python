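"""Fit the binding isotherms of a nanosensor titration.

Generates a lifetime (Hill) and an intensity (Langmuir) titration over the
assayed 100 fM – 150 nM range and recovers the binding parameters. The
half-saturation concentration EC50 is the apparent dissociation constant
K_app of the sensor.
"""

import tausense as ts
from tausense.synthetic import (
    REFERENCE_HILL_1X,
    REFERENCE_LANGMUIR_1X,
    default_concentration_grid,
)

grid = default_concentration_grid()  # 10 log-spaced points, 100 fM – 150 nM

# lifetime titration: tau2 4.183 -> 3.983 ns, EC50 18 pM, n = 1.89
series = ts.simulate_response_titration(
    REFERENCE_HILL_1X, grid, noise_sd=0.009, replicates=3, seed=7
)
fit = ts.fit_hill(series)
p = fit.params
print("Hill fit of the tau2 titration:")
print(f"  tau2_0   = {p.tau2_0:.3f} ns   tau2_max = {p.tau2_max:.3f} ns")
print(f"  EC50     = {p.ec50 * 1e12:.1f} ± {fit.stderr['ec50'] * 1e12:.1f} pM")
print(f"  n        = {p.n:.2f}    adj. R2 = {fit.r2_adj:.4f}")

# intensity titration: 34,399 -> 23,103 rfu, EC50 30 pM
lang = ts.fit_langmuir(
    ts.simulate_response_titration(
        REFERENCE_LANGMUIR_1X, grid, noise_sd=500.0, replicates=3, seed=7
    )
)
print("Langmuir fit of the intensity titration:")
print(f"  I0 = {lang.params.start:.0f} rfu   I_min = {lang.params.end:.0f} rfu")
print(f"  EC50 = {lang.params.k * 1e12:.1f} ± {lang.stderr['k'] * 1e12:.1f} pM")
# Both EC50 values sit in the low-pM range: the imprinted nanoparticles bind
# their template protein with picomolar apparent affinity.
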