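"""Langevin simulation of one fluctuation mode and spectrum recovery.

Integrates the overdamped shear-bending mode of the 7-um chromosome arm
with white thermal forcing, estimates the displacement autocorrelation,
and checks the fitted relaxation times against the closed-form spectrum.
(A single moderate run; longer or averaged runs tighten the recovery.)
"""

import numpy as np

from filarelax import (
    CHROMOSOME_DEFAULTS,
    empirical_acf,
    fit_biexponential,
    relaxation_times,
    simulate_mode,
)

props = CHROMOSOME_DEFAULTS.with_internal_friction(66.0, 162.0)
q = 2.2e5  # dominant wavenumber of the 7-um arm, m^-1

spec = relaxation_times(props, q)
print(f"closed-form spectrum: tau1 = {spec.tau1:.3f} s, tau2 = {spec.tau2:.3f} s")

traj = simulate_mode(props, q, dt=0.01, n_steps=2_000_000, seed=0)
print(
    f"simulated {traj.duration:.0f} s of signal "
    f"({traj.n_steps} steps at dt = {traj.dt} s)"
)

acf = empirical_acf(traj, max_lag=6.0)
res = fit_biexponential(acf)
print(
    f"fitted from simulation: tau1 = {res.model.tau1:.3f} s, "
    f"tau2 = {res.model.tau2:.3f} s"
)
print(
    "\nThe fast time is recovered tightly; the slow one is noisier\n"
    "because its amplitude carries under 1% of the variance when only\n"
    "the displacement equation is thermally forced."
)
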