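"""Mono- and bi-exponential fitting of autocorrelation series.

Two-exponential fitting is notoriously ill-conditioned when the two
times are within a factor of ~3 of each other, so the bi-exponential
fit uses multi-start nonlinear least squares with starts log-spaced
across the lag span, plus a start derived from the mono-exponential
fit.  Results are normalised to ``tau1 <= tau2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .beam import BiexponentialACF
from .properties import InvalidParameterError

DEFAULT_SEED = 20180803


@dataclass(frozen=True)
class ACFSeries:
    """An autocorrelation curve sampled on a lag grid.

    ``lags`` must be strictly increasing and nonnegative (seconds);
    ``values`` carry variance units.  Optional ``weights`` multiply the
    residuals in fitting.
    """

    lags: np.ndarray
    values: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        if lags.ndim != 1 or values.shape != lags.shape:
            raise InvalidParameterError("lags and values must be equal-length 1-D")
        if lags.size < 2:
            raise InvalidParameterError("need at least two lag points")
        if np.any(np.diff(lags) <= 0):
            raise InvalidParameterError("lags must be strictly increasing")
        if lags[0] < 0:
            raise InvalidParameterError("lags must be nonnegative")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            object.__setattr__(self, "weights", w)
            if w.shape != lags.shape:
                raise InvalidParameterError("weights must match lags")

    def __len__(self) -> int:
        return self.lags.size


@dataclass(frozen=True)
class FitResult:
    """Outcome of an autocorrelation fit.

    ``model`` is the fitted :class:`~filarelax.beam.BiexponentialACF`
    (mono-exponential when ``R2 == 0``); ``rmse`` is the lag-span
    normalised root-mean-square misfit, ``rmse_integral`` the raw
    square-root-of-integral variant; ``rss`` the residual sum of squares
    at the sample points.
    """

    model: BiexponentialACF
    rmse: float
    rmse_integral: float
    rss: float
    converged: bool
    n_restarts_used: int = 0
    message: str = ""


def fit_quality(series: ACFSeries, model) -> float:
    """Lag-span-normalised RMS misfit between a model curve and data.

    Computed as ``sqrt( trapezoid((data - model)^2 dT) / (Tmax - Tmin) )``
    so that a constant offset ``d`` gives exactly ``|d|``.  ``model``
    may be a :class:`BiexponentialACF` or any callable of the lags.
    """
    if len(series) < 2:
        raise InvalidParameterError("fit quality needs at least two points")
    resid = series.values - np.asarray(model(series.lags), dtype=float)
    span = series.lags[-1] - series.lags[0]
    integral = np.trapezoid(resid**2, series.lags)
    return float(np.sqrt(integral / span))


def fit_quality_integral(series: ACFSeries, model) -> float:
    """Square root of the raw integral of the squared misfit."""
    if len(series) < 2:
        raise InvalidParameterError("fit quality needs at least two points")
    resid = series.values - np.asarray(model(series.lags), dtype=float)
    return float(np.sqrt(np.trapezoid(resid**2, series.lags)))


def _tau_bounds(lags: np.ndarray) -> tuple[float, float]:
    dt = np.min(np.diff(lags))
    span = lags[-1] - lags[0]
    return dt / 100.0, span * 100.0


def _finish(series: ACFSeries, model: BiexponentialACF, rss: float,
            converged: bool, n_restarts: int, message: str) -> FitResult:
    return FitResult(
        model=model,
        rmse=fit_quality(series, model),
        rmse_integral=fit_quality_integral(series, model),
        rss=rss,
        converged=converged,
        n_restarts_used=n_restarts,
        message=message,
    )


def fit_monoexponential(series: ACFSeries, seed: int = DEFAULT_SEED) -> FitResult:
    """Least-squares fit of ``R * exp(-T/tau)`` to an ACF series.

    ``tau`` is kept positive by bounds.  Deterministic given the series
    (the seed only varies the small set of restart initialisations).
    """
    lags, vals = series.lags, series.values
    w = series.weights if series.weights is not None else 1.0
    lo, hi = _tau_bounds(lags)

    def resid(p):
        R, tau = p
        return (vals - R * np.exp(-lags / tau)) * w

    R0 = vals[0] if vals[0] != 0 else (np.max(np.abs(vals)) or 1.0)
    # crude decay-time guess from where the curve falls to R0/e
    below = np.nonzero(vals < R0 / np.e)[0]
    tau0 = lags[below[0]] if below.size and lags[below[0]] > 0 else (
        (lags[-1] - lags[0]) / 3.0
    )
    rng = np.random.default_rng(seed)
    starts = [(R0, tau0)]
    for f in (0.1, 1.0, 10.0):
        starts.append((R0, np.clip(tau0 * f * rng.uniform(0.8, 1.25), lo, hi)))
    best = None
    n_used = 0
    for R_i, tau_i in starts:
        n_used += 1
        sol = least_squares(
            resid,
            x0=[R_i, float(np.clip(tau_i, lo, hi))],
            bounds=([-np.inf, lo], [np.inf, hi]),
            method="trf",
        )
        if best is None or sol.cost < best.cost:
            best = sol
    R, tau = best.x
    at_bound = tau <= lo * 1.01 or tau >= hi * 0.99
    model = BiexponentialACF(R1=float(R), tau1=float(tau))
    return _finish(
        series, model, float(2.0 * best.cost),
        converged=bool(best.success and not at_bound),
        n_restarts=n_used,
        message="tau at bound" if at_bound else best.message,
    )


def _normalize_biexp(p) -> BiexponentialACF:
    R1, t1, R2, t2 = (float(v) for v in p)
    if t1 <= t2:
        return BiexponentialACF(R1=R1, tau1=t1, R2=R2, tau2=t2)
    return BiexponentialACF(R1=R2, tau1=t2, R2=R1, tau2=t1)


def fit_biexponential(series: ACFSeries, seed: int = DEFAULT_SEED) -> FitResult:
    """Multi-start least-squares fit of a two-exponential ACF model.

    At least ten starts with tau pairs log-spaced over the lag span plus
    a start seeded from the mono-exponential fit.  The result is
    normalised to ``tau1 <= tau2``; its residual sum of squares never
    exceeds the mono-exponential fit's (the mono model is nested).
    """
    if len(series) < 8:
        raise InvalidParameterError(
            "bi-exponential fitting needs at least 8 points"
        )
    lags, vals = series.lags, series.values
    w = series.weights if series.weights is not None else 1.0
    lo, hi = _tau_bounds(lags)

    def resid(p):
        R1, t1, R2, t2 = p
        return (vals - R1 * np.exp(-lags / t1) - R2 * np.exp(-lags / t2)) * w

    mono = fit_monoexponential(series, seed=seed)
    R_m, tau_m = mono.model.R1, mono.model.tau1
    span = lags[-1] - lags[0]
    taus = np.geomspace(
        max(lo, np.min(np.diff(lags))), min(hi, span * 3.0), 5
    )
    starts: list[tuple[float, float, float, float]] = []
    for i in range(len(taus)):
        for j in range(i + 1, len(taus)):
            starts.append((0.5 * R_m, taus[i], 0.5 * R_m, taus[j]))
    starts.append((0.5 * R_m, tau_m / 3.0, 0.5 * R_m, tau_m * 3.0))
    starts.append((R_m, tau_m, 0.0, min(hi, tau_m * 10.0)))

    best = None
    n_used = 0
    for R1_i, t1_i, R2_i, t2_i in starts:
        n_used += 1
        sol = least_squares(
            resid,
            x0=[R1_i, float(np.clip(t1_i, lo, hi)),
                R2_i, float(np.clip(t2_i, lo, hi))],
            bounds=([-np.inf, lo, -np.inf, lo], [np.inf, hi, np.inf, hi]),
            method="trf",
        )
        if best is None or sol.cost < best.cost:
            best = sol
    model = _normalize_biexp(best.x)
    rss = float(2.0 * best.cost)
    converged = bool(best.success) and rss <= mono.rss * (1.0 + 1e-9)
    if rss > mono.rss:
        # nesting guarantee: fall back to the mono solution as a
        # degenerate bi-exponential
        model = BiexponentialACF(
            R1=mono.model.R1, tau1=mono.model.tau1, R2=0.0,
            tau2=mono.model.tau1 * 10.0,
        )
        rss = mono.rss
    return _finish(series, model, rss, converged, n_used, best.message)
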