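"""Drag-dominated relaxation time versus filament length.

For a filament whose only dissipation channel is hydrodynamic drag, the
relaxation time of the mode with non-dimensional wavenumber
``q* = q L`` depends on length through two terms,

    tau_d(L) = eta/(B q*^4) L^4  +  eta/(kappa S q*^2) L^2,

the quartic term from bending against drag and the quadratic one from
shear against drag.  Fitting ``a L^4 + b L^2`` to measured (L, tau)
data therefore separates the two channels; the crossover length
``sqrt(b/a)`` marks where they contribute equally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .properties import FilamentProperties, InvalidParameterError


@dataclass(frozen=True)
class LengthScalingDataset:
    """(length, relaxation time) pairs, lengths strictly increasing (m, s)."""

    lengths: np.ndarray
    taus: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.lengths, dtype=float)
        t = np.asarray(self.taus, dtype=float)
        object.__setattr__(self, "lengths", L)
        object.__setattr__(self, "taus", t)
        if L.ndim != 1 or t.shape != L.shape:
            raise InvalidParameterError("lengths and taus must be equal-length 1-D")
        if np.any(L <= 0):
            raise InvalidParameterError("lengths must be positive")
        if np.any(np.diff(L) <= 0):
            raise InvalidParameterError("lengths must be strictly increasing")

    def __len__(self) -> int:
        return self.lengths.size


@dataclass(frozen=True)
class ScalingFit:
    """Fitted coefficients of tau = a L^4 + b L^2.

    ``coeff_L4`` (s m^-4) maps to eta/(B q*^4), ``coeff_L2`` (s m^-2) to
    eta/(kappa S q*^2); standard errors from the fit covariance.
    """

    coeff_L4: float
    coeff_L2: float
    se_L4: float
    se_L2: float
    log_space: bool

    def __call__(self, lengths) -> np.ndarray:
        L = np.asarray(lengths, dtype=float)
        return self.coeff_L4 * L**4 + self.coeff_L2 * L**2


def tau_drag_of_length(
    L: float, q_star: float, props: FilamentProperties
) -> float:
    """Drag-only relaxation time of the q* mode of a length-L filament.

    Identical to the drag-only dispersion relation evaluated at
    q = q*/L.
    """
    if not L > 0:
        raise InvalidParameterError(f"length must be positive, got {L}")
    if not q_star > 0:
        raise InvalidParameterError(f"q_star must be positive, got {q_star}")
    B, kS = props.B, props.kappa * props.S
    return (props.eta / (B * q_star**4)) * L**4 + (
        props.eta / (kS * q_star**2)
    ) * L**2


def fit_scaling(
    data: LengthScalingDataset,
    log_space: bool = True,
    seed: int | None = None,
) -> ScalingFit:
    """Least-squares fit of tau = a L^4 + b L^2 to a length-scaling dataset.

    Linear in the (L^4, L^2) basis.  With ``log_space=True`` (the
    default, suited to multiplicative scatter on log-log axes) the
    linear solution seeds a nonnegative nonlinear fit of
    ``log(a L^4 + b L^2)`` to ``log tau``.  ``seed`` is accepted for
    interface symmetry with the synthetic generators; the fit itself is
    deterministic.
    """
    if len(data) < 4:
        raise InvalidParameterError("need at least 4 points to fit both terms")
    L, tau = data.lengths, data.taus
    X = np.column_stack([L**4, L**2])
    coef, *_ = np.linalg.lstsq(X, tau, rcond=None)
    resid = tau - X @ coef
    dof = max(len(data) - 2, 1)
    sigma2 = float(resid @ resid) / dof
    try:
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError as e:
        raise InvalidParameterError(f"degenerate design matrix: {e}") from e
    if not log_space:
        return ScalingFit(
            coeff_L4=float(coef[0]), coeff_L2=float(coef[1]),
            se_L4=float(se[0]), se_L2=float(se[1]), log_space=False,
        )
    if np.any(tau <= 0):
        raise InvalidParameterError("log-space fitting needs positive taus")
    log_tau = np.log(tau)
    scale = float(np.median(tau))

    def resid_log(p):
        a, b = np.abs(p)
        return np.log(np.maximum(a * L**4 + b * L**2, 1e-300)) - log_tau

    x0 = np.maximum(coef, scale * 1e-12 / np.array([L[-1] ** 4, L[-1] ** 2]))
    sol = least_squares(resid_log, x0=x0, method="lm")
    a, b = (float(abs(v)) for v in sol.x)
    # standard errors from the log-space Jacobian
    J = sol.jac
    r = sol.fun
    dof = max(len(data) - 2, 1)
    s2 = float(r @ r) / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se_log = np.sqrt(np.abs(np.diag(cov)))
    except np.linalg.LinAlgError:
        se_log = np.array([math.nan, math.nan])
    return ScalingFit(
        coeff_L4=a, coeff_L2=b,
        se_L4=float(se_log[0]), se_L2=float(se_log[1]), log_space=True,
    )


def local_slope(data: LengthScalingDataset) -> np.ndarray:
    """Centred finite-difference slope of log tau versus log L.

    For drag-only two-term data the slope lies in (2, 4), approaching 2
    as L -> 0 and 4 as L -> infinity.  Returns one slope per interior
    point plus one-sided slopes at the ends (same length as the data).
    """
    if len(data) < 3:
        raise InvalidParameterError("need at least 3 points for local slopes")
    if np.any(data.taus <= 0):
        raise InvalidParameterError("slopes need positive relaxation times")
    x = np.log(data.lengths)
    y = np.log(data.taus)
    return np.gradient(y, x)


def crossover_length(fit: ScalingFit) -> float:
    """Length at which the L^4 and L^2 contributions are equal, sqrt(b/a).

    Infinite (and flagged by the math.inf return) when the quartic
    coefficient vanishes.
    """
    if fit.coeff_L4 < 0 or fit.coeff_L2 < 0:
        raise InvalidParameterError("crossover needs nonnegative coefficients")
    if fit.coeff_L4 == 0:
        return math.inf
    return math.sqrt(fit.coeff_L2 / fit.coeff_L4)


def theoretical_coefficients(
    q_star: float, props: FilamentProperties
) -> tuple[float, float]:
    """The (a, b) implied by filament properties at dimensionless q*."""
    if not q_star > 0:
        raise InvalidParameterError(f"q_star must be positive, got {q_star}")
    return (
        props.eta / (props.B * q_star**4),
        props.eta / (props.kappa * props.S * q_star**2),
    )
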