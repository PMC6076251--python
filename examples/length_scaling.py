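"""Drag-dominated relaxation time versus microtubule length.

Generates a noisy synthetic relaxation-time-versus-length dataset for
microtubule-like filaments (2-30 um), fits the two-term law
tau = a L^4 + b L^2, and reports the crossover length separating the
shear-dominated (L^2) from the bending-dominated (L^4) regime.
"""

import numpy as np

from filarelax import (
    MICROTUBULE_DEFAULTS,
    crossover_length,
    fit_scaling,
    local_slope,
    make_synthetic_scaling,
    theoretical_coefficients,
)

data = make_synthetic_scaling(noise_cv=0.15, seed=7)
fit = fit_scaling(data, log_space=True)
a_true, b_true = theoretical_coefficients(np.pi / 2, MICROTUBULE_DEFAULTS)

print(f"fitted  a (L^4 coeff) = {fit.coeff_L4:.3e} s/m^4  (true {a_true:.3e})")
print(f"fitted  b (L^2 coeff) = {fit.coeff_L2:.3e} s/m^2  (true {b_true:.3e})")
print(f"crossover length      = {crossover_length(fit) * 1e6:.1f} um")

smooth = make_synthetic_scaling(noise_cv=0.0)
slopes = local_slope(smooth)
print(
    f"log-log slope (theory): {slopes[0]:.2f} at "
    f"L = {smooth.lengths[0] * 1e6:.1f} um -> {slopes[-1]:.2f} at "
    f"L = {smooth.lengths[-1] * 1e6:.1f} um"
)
print(
    "\nShort filaments relax on the L^2 (shear against drag) branch,\n"
    "long ones on the L^4 (bending against drag) branch; the crossover\n"
    "near 10 um reproduces the behaviour seen in microtubule\n"
    "fluctuation experiments."
)
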