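"""Inversion of fitted relaxation times into internal-friction coefficients.

Three routes, matching the three coefficient columns an experimenter
would tabulate:

* ``invert_large_q`` — the wavenumber-independent large-q limits
  (eta_b = tau1 * E, eta_s = tau2 * kappa * G);
* ``invert_eb`` — the bending-only (worm-like chain) relation at a
  given wavenumber;
* ``invert_full`` — exact inversion of the coupled two-timescale
  relation at a given wavenumber by root finding in log-coefficient
  space (which enforces positivity and conditions the near-cancelling
  system), seeded from the large-q estimate.

A bi-exponential fit does not label which fitted time is the fast one;
``disambiguate_assignment`` picks the assignment whose full-model and
large-q coefficient estimates agree best, requiring positivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from .beam import relaxation_times
from .properties import FilamentProperties, InvalidParameterError


class UnphysicalResultError(ValueError):
    """No positive-coefficient solution reproduces the requested times."""


@dataclass(frozen=True)
class CoefficientEstimate:
    """Internal-friction coefficients inferred from relaxation times.

    ``eta_b`` and ``eta_s`` in kg m^-1 s^-1 (``eta_s`` is ``nan`` for the
    bending-only route, which cannot see shear).  ``physical`` is False
    when a negative coefficient was obtained; such estimates are flagged
    rather than silently returned.
    """

    eta_b: float
    eta_s: float
    method: str
    wavenumber_used: float = math.nan
    physical: bool = True
    residual: float = math.nan


def dominant_wavenumber(L: float) -> float:
    """Wavenumber of the lowest cantilever bending mode, q = pi/(2L)."""
    if not L > 0:
        raise InvalidParameterError(f"length must be positive, got {L}")
    return math.pi / (2.0 * L)


def invert_large_q(
    tau1: float, tau2: float, props: FilamentProperties
) -> CoefficientEstimate:
    """Coefficients from the large-wavenumber limits.

    eta_b = tau1 * B / I = tau1 * E and eta_s = tau2 * kappa * S / A =
    tau2 * kappa * G.
    """
    if tau1 < 0 or tau2 < 0:
        raise InvalidParameterError("relaxation times must be nonnegative")
    eta_b = tau1 * props.E
    eta_s = tau2 * props.kappa * props.G
    return CoefficientEstimate(
        eta_b=eta_b, eta_s=eta_s, method="large_q_limit",
        physical=eta_b >= 0 and eta_s >= 0,
    )


def invert_eb(
    tau: float, q: float, props: FilamentProperties
) -> CoefficientEstimate:
    """Bending coefficient from the bending-only relation at wavenumber q.

    eta_b = (tau * B * q^4 - eta) / (I * q^4) = tau * E - eta/(I q^4);
    a negative result (drag exceeding the fitted time's dissipation) is
    flagged unphysical.
    """
    if not q > 0:
        raise InvalidParameterError(f"wavenumber must be positive, got {q}")
    eta_b = tau * props.E - props.eta / (props.I * q**4)
    return CoefficientEstimate(
        eta_b=eta_b, eta_s=math.nan, method="eb",
        wavenumber_used=q, physical=eta_b >= 0,
    )


def invert_full_candidates(
    tau1: float, tau2: float, q: float, props: FilamentProperties
) -> list[tuple[float, float]]:
    """Both coefficient pairs whose spectrum at ``q`` is {tau1, tau2}.

    At fixed wavenumber the rate-sum and rate-product relations give one
    linear and one bilinear equation in (eta_b, eta_s); eliminating
    eta_s leaves a quadratic in eta_b, so the inversion generically has
    two solutions.  They correspond to the two ways of assigning the
    bending-like branch to the fast or the slow time (a bi-exponential
    fit cannot distinguish them).  Candidates may carry negative
    entries when the requested times are unreachable with positive
    coefficients; callers filter on physicality.
    """
    if not (0 < tau1 <= tau2):
        raise InvalidParameterError("need 0 < tau1 <= tau2")
    if not q > 0:
        raise InvalidParameterError(f"wavenumber must be positive, got {q}")
    lam_fast, lam_slow = 1.0 / tau1, 1.0 / tau2
    A, I = props.A, props.I
    B, kS = props.B, props.kappa * props.S
    eta = props.eta
    detK = B * kS * q**4
    # target detC and target internal part of trace(adj(C) K)
    u = detK / (lam_fast * lam_slow)
    W = detK * (lam_fast + lam_slow) / (lam_fast * lam_slow) \
        - eta * B * q**2 - eta * kS
    c1, c2 = I * kS * q**4, A * B * q**4
    d0, d1, d2 = I * A * q**4, eta * I * q**2, eta * A
    # a x^2 - b x + c = 0 for x = eta_b, stable root extraction
    a = d0 * c1
    b = d0 * W + d1 * c2 - d2 * c1
    c = u * c2 - d2 * W
    sq = math.sqrt(max(b * b - 4.0 * a * c, 0.0))
    r1 = (b + sq) / (2.0 * a) if b >= 0 else (b - sq) / (2.0 * a)
    r2 = c / (a * r1) if r1 != 0.0 else 0.0
    return [(eb, (W - c1 * eb) / c2) for eb in sorted({r1, r2})]


def invert_full(
    tau1: float,
    tau2: float,
    q: float,
    props: FilamentProperties,
    rtol: float = 1e-9,
) -> CoefficientEstimate:
    """Exact inversion of the two-timescale relation at wavenumber q.

    Finds (eta_b, eta_s) such that the coupled shear-bending model's two
    relaxation times at ``q`` equal ``(tau1, tau2)``.  The closed-form
    candidate nearest (in log space) to the large-wavenumber-limit seed
    is selected, polished by Newton root finding in log-coefficient
    space, and verified by forward evaluation to relative residual
    below ``rtol``; otherwise an :class:`UnphysicalResultError` with
    diagnostics is raised.
    """
    if not (0 < tau1 < tau2):
        raise InvalidParameterError("need 0 < tau1 < tau2")
    candidates = [
        (eb, es)
        for eb, es in invert_full_candidates(tau1, tau2, q, props)
        if eb > 0 and es > 0
    ]
    if not candidates:
        raise UnphysicalResultError(
            f"no positive-coefficient solution reproduces "
            f"(tau1, tau2) = ({tau1:g}, {tau2:g}) at q = {q:g}; "
            f"closed-form candidates: "
            f"{invert_full_candidates(tau1, tau2, q, props)}"
        )
    seed = invert_large_q(tau1, tau2, props)
    ref = np.log([max(seed.eta_b, 1e-300), max(seed.eta_s, 1e-300)])

    def logdist(pair):
        return float(
            np.max(np.abs(np.log(np.array(pair)) - ref))
        )

    eb0, es0 = min(candidates, key=logdist)

    def residual(logx):
        eb, es = np.exp(logx)
        spec = relaxation_times(props.with_internal_friction(eb, es), q)
        return [spec.tau1 / tau1 - 1.0, spec.tau2 / tau2 - 1.0]

    x0 = np.log([eb0, es0])
    res = float(np.max(np.abs(residual(x0))))
    if res > rtol:
        sol = root(residual, x0, method="hybr", tol=1e-14)
        res = float(np.max(np.abs(residual(sol.x))))
        x0 = sol.x
    if res > rtol:
        raise UnphysicalResultError(
            "inversion did not converge: best residual "
            f"{res:.3e} at eta_b={math.exp(x0[0]):.4g}, "
            f"eta_s={math.exp(x0[1]):.4g}"
        )
    eta_b, eta_s = (float(v) for v in np.exp(x0))
    return CoefficientEstimate(
        eta_b=eta_b, eta_s=eta_s, method="full_eq_two_timescale",
        wavenumber_used=q, physical=True, residual=res,
    )


def disambiguate_assignment(
    tau_pair_a: tuple[float, float],
    tau_pair_b: tuple[float, float],
    q: float,
    props: FilamentProperties,
) -> tuple[tuple[float, float], CoefficientEstimate, float]:
    """Choose between the two orderings a bi-exponential fit produces.

    For each candidate (tau_fast, tau_slow) assignment, invert via the
    full relation at ``q`` and via the large-q limit, and score the
    assignment by the worse of the two coefficientwise relative
    discrepancies.  The physically consistent assignment minimises that
    discrepancy.  Returns the chosen pair, its full-model estimate, and
    the discrepancy; raises if neither assignment admits a physical
    solution.
    """

    def score(pair):
        t1, t2 = pair
        if math.isclose(t1, t2, rel_tol=1e-12):
            return None, 0.0, "indistinct"
        if not t1 < t2:
            return None, math.inf, "fast time not smaller"
        try:
            full = invert_full(t1, t2, q, props)
        except (UnphysicalResultError, InvalidParameterError) as e:
            return None, math.inf, str(e)
        limit = invert_large_q(t1, t2, props)
        if not (full.physical and limit.physical):
            return None, math.inf, "negative coefficients"
        disc = max(
            abs(full.eta_b / limit.eta_b - 1.0) if limit.eta_b else 0.0,
            abs(full.eta_s / limit.eta_s - 1.0) if limit.eta_s else 0.0,
        )
        return full, disc, ""

    ta, tb = tuple(tau_pair_a), tuple(tau_pair_b)
    if math.isclose(ta[0], ta[1], rel_tol=1e-12):
        est = invert_large_q(ta[0], ta[1], props)
        return ta, est, 0.0
    est_a, disc_a, msg_a = score(ta)
    est_b, disc_b, msg_b = score(tb)
    if est_a is None and est_b is None:
        raise UnphysicalResultError(
            f"both assignments unphysical: (a) {msg_a}; (b) {msg_b}"
        )
    if est_b is None or (est_a is not None and disc_a <= disc_b):
        return ta, est_a, disc_a
    return tb, est_b, disc_b
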