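"""Stochastic simulation of a single shear-bending fluctuation mode.

Euler-Maruyama integration of the overdamped mode dynamics
``C zdot = -K z + f`` with white thermal forcing on the displacement
component (optionally also on the rotation component, for exploring
fluctuation-dissipation-consistent variants).  Because the system is
linear, the Euler-Maruyama recursion ``z_{n+1} = A z_n + w_n`` is
evaluated exactly through a diagonalised recursive filter, which makes
million-step runs cheap; a plain loop fallback covers the rare
non-diagonalisable case.  Synthetic-dataset factories emulate the two
experiment types the model addresses: noisy bi-exponential
autocorrelations of a fluctuating chromosome arm, and relaxation-time
versus length tables of fluctuating microtubules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from statsmodels.tsa.stattools import acovf

from .beam import BiexponentialACF, overdamped_matrices, relaxation_times
from .fit import ACFSeries
from .properties import FilamentProperties, InvalidParameterError
from .scaling import LengthScalingDataset, tau_drag_of_length

#: default microtubule-like parameters for length-scaling synthesis:
#: stiff in bending (E ~ GPa) but orders of magnitude softer in shear
#: (G ~ kPa), standard 12.5 nm outer radius, slender-body drag in water.
MICROTUBULE_DEFAULTS = FilamentProperties(
    E=1.2e9, G=1.5e3, r=12.5e-9, kappa=0.75, eta=2.0e-3
)

#: chromosome-arm parameters used throughout the worked examples.
CHROMOSOME_DEFAULTS = FilamentProperties(
    E=500.0, G=227.0, r=1.0e-6, kappa=0.75, eta=1.0e-3
)


@dataclass(frozen=True)
class ModeTrajectory:
    """Sampled (displacement, rotation) trajectory of one Fourier mode."""

    dt: float
    displacement: np.ndarray
    rotation: np.ndarray
    q: float
    seed: int

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise InvalidParameterError("dt must be positive")

    @property
    def n_steps(self) -> int:
        return self.displacement.size

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt


def _stability_dt(props: FilamentProperties, q: float) -> float:
    """Largest admissible time step: a tenth of the fast relaxation time."""
    return relaxation_times(props, q).tau1 / 10.0


def simulate_mode(
    props: FilamentProperties,
    q: float,
    noise_level: float = 1.0,
    dt: float = 1e-3,
    n_steps: int = 100_000,
    seed: int = 0,
    rotational_forcing: bool = False,
) -> ModeTrajectory:
    """Euler-Maruyama simulation of the mode at wavenumber ``q``.

    White forcing with two-sided spectral density ``noise_level`` acts
    on the displacement equation (discretised as i.i.d. per-step forces
    of variance ``noise_level/dt``, the convention under which the
    stationary statistics match :func:`~filarelax.beam.acf_model`); set
    ``rotational_forcing`` to add an independent source of the same
    density on the rotation equation.  ``dt`` must stay below a tenth
    of the fast relaxation time.  Bit-reproducible given ``seed``.
    """
    if n_steps < 1:
        raise InvalidParameterError("n_steps must be >= 1")
    if noise_level < 0:
        raise InvalidParameterError("noise_level must be >= 0")
    dt_max = _stability_dt(props, q)
    if dt > dt_max:
        raise InvalidParameterError(
            f"dt = {dt:g} exceeds the stability bound tau_fast/10 = {dt_max:g}"
        )
    C, K = overdamped_matrices(props, q)
    rng = np.random.default_rng(seed)
    amp = math.sqrt(noise_level * dt)

    if props.eta_b == 0 and props.eta_s == 0:
        # C is singular: the rotation is slaved to the displacement by
        # the elastic constraint, leaving a scalar OU process on u.
        if props.eta == 0:
            raise InvalidParameterError("no dissipation channel to integrate")
        k_eff = (K[0, 0] * K[1, 1] - K[0, 1] ** 2) / K[0, 0]
        a = 1.0 - dt * k_eff / props.eta
        g = rng.standard_normal(n_steps)
        u = lfilter([amp / props.eta], [1.0, -a], g)
        phi = -(K[0, 1] / K[0, 0]) * u
        return ModeTrajectory(
            dt=dt, displacement=u, rotation=phi, q=q, seed=seed
        )

    Cinv = np.linalg.inv(C)
    A = np.eye(2) - dt * (Cinv @ K)
    sources = [Cinv @ np.array([0.0, 1.0])]
    if rotational_forcing:
        sources.append(Cinv @ np.array([1.0, 0.0]))
    evals, V = np.linalg.eig(A)
    if np.iscomplexobj(evals) and np.max(np.abs(evals.imag)) > 0:
        return _simulate_loop(A, sources, amp, dt, n_steps, q, seed, rng)
    evals, V = evals.real, V.real
    Vinv = np.linalg.inv(V)
    z = np.zeros((2, n_steps))
    for v in sources:
        g = rng.standard_normal(n_steps)
        c = Vinv @ (amp * v)
        y = np.vstack(
            [lfilter([c[i]], [1.0, -evals[i]], g) for i in range(2)]
        )
        z += V @ y
    return ModeTrajectory(
        dt=dt, displacement=z[1], rotation=z[0], q=q, seed=seed
    )


def _simulate_loop(A, sources, amp, dt, n_steps, q, seed, rng):
    """Plain Euler-Maruyama loop (fallback for non-diagonalisable A)."""
    z = np.zeros(2)
    out = np.empty((2, n_steps))
    gs = [rng.standard_normal(n_steps) for _ in sources]
    for n in range(n_steps):
        z = A @ z
        for v, g in zip(sources, gs):
            z = z + amp * v * g[n]
        out[:, n] = z
    return ModeTrajectory(
        dt=dt, displacement=out[1], rotation=out[0], q=q, seed=seed
    )


def empirical_acf(traj: ModeTrajectory, max_lag: float) -> ACFSeries:
    """Biased sample autocovariance of the displacement, up to ``max_lag``.

    The zero-lag value is the sample variance.  ``max_lag`` must not
    exceed a fifth of the trajectory duration (longer lags are too noisy
    to be meaningful).
    """
    if not max_lag > 0:
        raise InvalidParameterError("max_lag must be positive")
    if max_lag >= traj.duration / 5.0:
        raise InvalidParameterError(
            f"max_lag = {max_lag:g} too large; must be < duration/5 = "
            f"{traj.duration / 5.0:g}"
        )
    n_lags = int(max_lag / traj.dt)
    acov = acovf(traj.displacement, fft=True, demean=True, nlag=n_lags)
    lags = np.arange(n_lags + 1) * traj.dt
    return ACFSeries(lags=lags, values=acov)


def make_synthetic_acf(
    model: BiexponentialACF,
    lag_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ACFSeries:
    """Model autocorrelation curve plus i.i.d. Gaussian measurement noise."""
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    lags = np.asarray(lag_grid, dtype=float)
    rng = np.random.default_rng(seed)
    values = model(lags)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=lags.shape)
    return ACFSeries(lags=lags, values=values)


def default_scaling_lengths(n: int = 24) -> np.ndarray:
    """Log-spaced filament lengths over the 2-30 um experimental span."""
    return np.geomspace(2e-6, 30e-6, n)


def make_synthetic_scaling(
    props: FilamentProperties = MICROTUBULE_DEFAULTS,
    lengths=None,
    q_star: float = math.pi / 2.0,
    noise_cv: float = 0.15,
    seed: int = 0,
) -> LengthScalingDataset:
    """Noisy relaxation-time-versus-length table for a drag-dominated filament.

    Relaxation times follow the two-term drag-only law at dimensionless
    wavenumber ``q_star``, multiplied by unit-mean lognormal noise with
    coefficient of variation ``noise_cv`` (the multiplicative scatter
    characteristic of log-log experimental data).
    """
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")
    L = default_scaling_lengths() if lengths is None else np.asarray(
        lengths, dtype=float
    )
    tau = np.array([tau_drag_of_length(x, q_star, props) for x in L])
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(noise_cv**2))
        tau = tau * rng.lognormal(-0.5 * sigma**2, sigma, size=L.shape)
    return LengthScalingDataset(lengths=L, taus=tau)


def superpose_modes(
    L: float, amplitudes, x
) -> np.ndarray:
    """Filament shape from sinusoidal cantilever modes (visual convenience).

    Sums ``a_n sin(q_n x)`` with ``q_n = (2n - 1) pi / (2 L)`` — an
    approximation to true clamped-free eigenfunctions, intended only for
    illustrating mode content.
    """
    if not L > 0:
        raise InvalidParameterError("length must be positive")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for n, a in enumerate(np.asarray(amplitudes, dtype=float), start=1):
        out += a * np.sin((2 * n - 1) * math.pi / (2.0 * L) * x)
    return out
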