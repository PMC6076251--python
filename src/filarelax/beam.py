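"""Per-wavenumber overdamped shear-bending dynamics of a filament.

The filament is modelled as a Timoshenko beam driven by white thermal
forcing and damped by hydrodynamic drag (coefficient ``eta`` per unit
length) and by internal friction in the bending and shear deformation
rates (coefficients ``eta_b`` and ``eta_s``).  After a spatial Fourier
transform at wavenumber ``q`` the two fields — cross-section rotation
``phi`` and transverse displacement ``u`` — obey a linear overdamped
system ``C zdot + K z = f`` with 2x2 symmetric positive-semidefinite
damping ``C`` and stiffness ``K`` matrices.

The displacement autocorrelation of that system decays as a sum of two
exponentials; the two relaxation times are the reciprocals of the roots
of ``detC * lam**2 - Nbar * lam + detK = 0``.  Naive evaluation of the
three scalar invariants from matrix entries loses several digits to
cancellation for realistic parameters, so this module always evaluates
them through cancellation-free closed forms and extracts the slow root
by Vieta's product rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .properties import FilamentProperties, InvalidParameterError


class DegenerateSystemError(ValueError):
    """All dissipation channels vanish: no relaxation times exist."""


class DegenerateSpectrumError(ValueError):
    """The two decay rates coincide; partial fractions are undefined."""


@dataclass(frozen=True)
class RelaxationSpectrum:
    """The two energy relaxation times at one wavenumber.

    ``tau1 <= tau2`` by convention.  ``quad_M``, ``quad_N``, ``quad_P``
    are the invariants of the quadratic ``M x**2 - N x + P = 0`` whose
    roots are the squared decay rates ``x = 1/tau**2``.  ``tau1`` is
    ``inf``-free: for a drag-only filament the spectrum is
    mono-exponential and ``tau1 == tau2``.
    """

    q: float
    tau1: float
    tau2: float
    quad_M: float
    quad_N: float
    quad_P: float

    @property
    def rates(self) -> tuple[float, float]:
        """Decay rates (1/tau2, 1/tau1) ordered slow, fast."""
        return 1.0 / self.tau2, 1.0 / self.tau1


@dataclass(frozen=True)
class BiexponentialACF:
    """Autocorrelation model R1*exp(-T/tau1) + R2*exp(-T/tau2).

    The mono-exponential model is the degenerate case ``R2 == 0``.
    Amplitudes carry variance units; the value at zero lag is R1 + R2.
    """

    R1: float
    tau1: float
    R2: float = 0.0
    tau2: float = math.inf

    def __post_init__(self) -> None:
        if not self.tau1 > 0 or not self.tau2 > 0:
            raise InvalidParameterError("relaxation times must be positive")

    @property
    def variance(self) -> float:
        """Zero-lag value R1 + R2."""
        return self.R1 + self.R2

    def __call__(self, lags) -> np.ndarray:
        lags = np.asarray(lags, dtype=float)
        out = self.R1 * np.exp(-lags / self.tau1)
        if self.R2 != 0.0 and np.isfinite(self.tau2):
            out = out + self.R2 * np.exp(-lags / self.tau2)
        return out


def overdamped_matrices(
    props: FilamentProperties, q: float
) -> tuple[np.ndarray, np.ndarray]:
    """Damping and stiffness matrices of the Fourier-mode dynamics.

    Returns the pair ``(C, K)`` over the state ``z = (phi, u)`` such that
    ``C zdot + K z = f`` reproduces the overdamped shear-bending
    equations at wavenumber ``q``.  Both matrices are real symmetric
    positive semidefinite in this sign convention.
    """
    if not q > 0:
        raise InvalidParameterError(f"wavenumber must be positive, got {q}")
    A, I = props.A, props.I
    B, kS = props.B, props.kappa * props.S
    C = np.array(
        [
            [props.eta_b * I * q**2 + props.eta_s * A, q * props.eta_s * A],
            [q * props.eta_s * A, props.eta_s * A * q**2 + props.eta],
        ]
    )
    K = np.array(
        [
            [B * q**2 + kS, q * kS],
            [q * kS, kS * q**2],
        ]
    )
    return C, K


def _scalar_invariants(
    props: FilamentProperties, q: float
) -> tuple[float, float, float]:
    """Cancellation-free detC, Nbar = trace(adj(C) K), detK.

    These are the coefficients of the rate quadratic
    detC * lam^2 - Nbar * lam + detK = 0.  Expanding the determinants
    from matrix entries cancels 4+ digits for Table-like parameters, so
    the closed forms below (in which every monomial is nonnegative) are
    mandatory.
    """
    A, I = props.A, props.I
    B, kS = props.B, props.kappa * props.S
    eta, eb, es = props.eta, props.eta_b, props.eta_s
    detC = eb * es * I * A * q**4 + eta * (eb * I * q**2 + es * A)
    Nbar = (eb * I * kS + es * A * B) * q**4 + eta * B * q**2 + eta * kS
    detK = B * kS * q**4
    return detC, Nbar, detK


def quadratic_invariants(
    props: FilamentProperties, q: float
) -> tuple[float, float, float]:
    """Invariants (M, N, P) of the squared-rate quadratic.

    The two squared decay rates ``x = 1/tau**2`` are the roots of
    ``M x**2 - N x + P = 0`` with ``M = detC**2``,
    ``N = Nbar**2 - 2 detC detK`` and ``P = detK**2``.
    """
    if not q > 0:
        raise InvalidParameterError(f"wavenumber must be positive, got {q}")
    if props.eta == 0 and props.eta_b == 0 and props.eta_s == 0:
        raise DegenerateSystemError(
            "all dissipation coefficients vanish; relaxation is undefined"
        )
    detC, Nbar, detK = _scalar_invariants(props, q)
    return detC**2, Nbar**2 - 2.0 * detC * detK, detK**2


def decay_rates(props: FilamentProperties, q: float) -> tuple[float, float]:
    """The two decay rates (lam_slow, lam_fast), numerically stable.

    The fast rate comes from the stable branch of the quadratic formula;
    the slow rate from Vieta's product ``lam_slow * lam_fast =
    detK/detC``, avoiding the catastrophic subtraction that otherwise
    destroys it.  When ``detC`` vanishes (drag-only filament) the
    quadratic degenerates to the single finite rate ``detK/Nbar`` and
    that rate is returned twice.
    """
    if props.eta == 0 and props.eta_b == 0 and props.eta_s == 0:
        raise DegenerateSystemError(
            "all dissipation coefficients vanish; relaxation is undefined"
        )
    detC, Nbar, detK = _scalar_invariants(props, q)
    if detC == 0.0:
        if Nbar == 0.0:
            raise DegenerateSystemError("detC = 0 and Nbar = 0")
        lam = detK / Nbar
        return lam, lam
    disc = Nbar * Nbar - 4.0 * detC * detK
    disc = max(disc, 0.0)
    lam_fast = (Nbar + math.sqrt(disc)) / (2.0 * detC)
    lam_slow = detK / (detC * lam_fast)
    return lam_slow, lam_fast


def relaxation_times(props: FilamentProperties, q: float) -> RelaxationSpectrum:
    """Both relaxation times of the coupled shear-bending mode at ``q``.

    Returns a :class:`RelaxationSpectrum` with ``tau1 <= tau2`` (the
    fast time first).  Branch identity (bending-like vs shear-like) is
    not encoded in the index; compare against :func:`large_q_limits`.
    """
    if not q > 0:
        raise InvalidParameterError(f"wavenumber must be positive, got {q}")
    lam_slow, lam_fast = decay_rates(props, q)
    M, N, P = quadratic_invariants(props, q)
    return RelaxationSpectrum(
        q=q,
        tau1=1.0 / lam_fast,
        tau2=1.0 / lam_slow,
        quad_M=M,
        quad_N=N,
        quad_P=P,
    )


def relaxation_time_eb(props: FilamentProperties, q: float) -> float:
    """Single relaxation time of the bending-only (worm-like chain) model.

    tau = (eta + eta_b * I * q^4) / (B * q^4); the large-q limit is
    eta_b * I / B = eta_b / E.
    """
    if not q > 0:
        raise InvalidParameterError(f"wavenumber must be positive, got {q}")
    return (props.eta + props.eta_b * props.I * q**4) / (props.B * q**4)


def relaxation_time_drag(props: FilamentProperties, q: float) -> float:
    """Relaxation time of the drag-only shear-bending filament.

    tau_d = (kappa*S*eta + B*eta*q^2) / (kappa*S*B*q^4); strictly
    decreasing in q and approaching eta/(B q^4) as q -> 0.
    """
    if not q > 0:
        raise InvalidParameterError(f"wavenumber must be positive, got {q}")
    B, kS = props.B, props.kappa * props.S
    return (kS * props.eta + B * props.eta * q**2) / (kS * B * q**4)


def large_q_limits(props: FilamentProperties) -> tuple[float, float]:
    """Wavenumber-independent limits (tau1, tau2) as q -> infinity.

    tau1 -> eta_b*I/B = eta_b/E (bending-like) and
    tau2 -> eta_s*A/(kappa*S) = eta_s/(kappa*G) (shear-like).
    """
    return props.eta_b / props.E, props.eta_s / (props.kappa * props.G)


def small_q_limits(props: FilamentProperties, q: float) -> tuple[float, float]:
    """Limits (tau1, tau2) as q -> 0 at wavenumber q.

    tau1 -> eta_s*A/(kappa*S) and tau2 -> eta/(B q^4), the divergent
    drag-dominated branch shared with the bending-only model.
    """
    if not q > 0:
        raise InvalidParameterError(f"wavenumber must be positive, got {q}")
    return props.eta_s / (props.kappa * props.G), props.eta / (props.B * q**4)


def acf_model(
    props: FilamentProperties, q: float, noise_level: float = 1.0
) -> BiexponentialACF:
    """Model displacement autocorrelation at wavenumber ``q``.

    White forcing of spectral density ``noise_level`` acts on the
    displacement equation only.  The displacement power spectrum

        S_u(w) = noise_level * (k11^2 + w^2 c11^2)
                 / [detC^2 (w^2 + lam1^2)(w^2 + lam2^2)]

    is resolved by partial fractions into the two Lorentzians whose
    inverse transforms give the amplitudes

        R_i = noise_level * (k11^2 - lam_i^2 c11^2)
              / (2 detC^2 lam_i (lam_j^2 - lam_i^2)).

    ``R1 + R2`` equals the zero-lag variance (the integral of ``S_u``
    over frequency divided by 2 pi).  For a drag-only filament the
    spectrum is a single Lorentzian and a mono-exponential model is
    returned.
    """
    if noise_level < 0:
        raise InvalidParameterError("noise_level must be >= 0")
    C, K = overdamped_matrices(props, q)
    if props.eta_b == 0 and props.eta_s == 0:
        # phi is slaved to u: scalar OU process eta*udot = -k_eff*u + f
        # with k_eff = detK/k11, variance noise_level/(2 k_eff eta).
        tau_d = relaxation_time_drag(props, q)
        k_eff = (K[0, 0] * K[1, 1] - K[0, 1] ** 2) / K[0, 0]
        R = noise_level / (2.0 * k_eff * props.eta)
        return BiexponentialACF(R1=R, tau1=tau_d)
    lam_slow, lam_fast = decay_rates(props, q)
    if lam_slow == lam_fast:
        raise DegenerateSpectrumError("repeated decay rate; ACF not biexponential")
    detC = _scalar_invariants(props, q)[0]
    c11, k11 = C[0, 0], K[0, 0]

    def residue(lam_i: float, lam_j: float) -> float:
        return (
            noise_level
            * (k11**2 - lam_i**2 * c11**2)
            / (2.0 * detC**2 * lam_i * (lam_j**2 - lam_i**2))
        )

    R_fast = residue(lam_fast, lam_slow)
    R_slow = residue(lam_slow, lam_fast)
    return BiexponentialACF(
        R1=R_fast, tau1=1.0 / lam_fast, R2=R_slow, tau2=1.0 / lam_slow
    )
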