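"""From a noisy autocorrelation to internal-friction coefficients.

Generates a synthetic bi-exponential autocorrelation for the 7-um
chromosome arm, fits both exponential models, resolves the two-solution
ambiguity of the fit, and inverts the chosen times into bending and
shear internal-friction coefficients.
"""

import numpy as np

from filarelax import (
    CHROMOSOME_DEFAULTS,
    acf_model,
    disambiguate_assignment,
    dominant_wavenumber,
    fit_biexponential,
    fit_monoexponential,
    invert_large_q,
    make_synthetic_acf,
)

q = dominant_wavenumber(7e-6)  # 0.22 um^-1, lowest cantilever mode
truth = CHROMOSOME_DEFAULTS.with_internal_friction(66.0, 162.0)
model = acf_model(truth, q)

lags = np.linspace(0.0, 8.0, 2000)
series = make_synthetic_acf(model, lags, noise_sd=0.01 * model.R2, seed=1)

mono = fit_monoexponential(series)
biexp = fit_biexponential(series)
print(f"mono fit:   tau = {mono.model.tau1:.3f} s, rmse = {mono.rmse:.2e}")
print(
    f"biexp fit:  tau1 = {biexp.model.tau1:.3f} s, "
    f"tau2 = {biexp.model.tau2:.3f} s, rmse = {biexp.rmse:.2e}"
)

t1, t2 = biexp.model.tau1, biexp.model.tau2
chosen, est, disc = disambiguate_assignment(
    (t1, t2), (t2, t1), q, CHROMOSOME_DEFAULTS
)
limit = invert_large_q(*chosen, CHROMOSOME_DEFAULTS)
print(f"\naccepted assignment: tau1 = {chosen[0]:.3f}, tau2 = {chosen[1]:.3f}")
print(
    f"full-model inversion:  eta_b = {est.eta_b:.1f}, "
    f"eta_s = {est.eta_s:.1f} kg/(m.s)"
)
print(
    f"large-q-limit check:   eta_b = {limit.eta_b:.1f}, "
    f"eta_s = {limit.eta_s:.1f} kg/(m.s)  (discrepancy {disc:.1%})"
)
print(
    "\nThe two-exponential fit beats the single-exponential one (smaller\n"
    "rmse), and the inverted coefficients recover the pair (66, 162)\n"
    "used to generate the data."
)
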