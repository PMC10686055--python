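"""Growth and fermentation kinetics from OD600 and cumulative-CO2 curves.

Five parameters summarize one fermentation:

* ``k``   — maximum cell population (logistic carrying capacity, OD units)
* ``r``   — maximum specific growth rate (1/h, logistic intrinsic rate)
* ``vmax``— maximum CO2 production rate (g/h, finite differences)
* ``lagtime`` — time to produce 1 g of CO2 (h)
* ``t80`` — time to reach 80% of attenuation, i.e. 80% of the maximum
  theoretical CO2 from the medium's sugars (h)

Thresholds that a curve never attains (slow or stuck fermentations) are
reported as ``None`` — an explicit "not reached" marker, never a large
placeholder number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .media import MediumSpec, theoretical_co2_max

__all__ = [
    "GrowthCurve",
    "CO2Curve",
    "LogisticFit",
    "KineticsSummary",
    "logistic",
    "fit_logistic",
    "attenuation_time",
    "max_co2_rate",
    "lag_time",
    "summarize",
]


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time course (times in hours, strictly increasing)."""

    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and od must be 1-D and equal length")
        if t.size < 5:
            raise ValueError("need at least 5 points to fit growth")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("OD must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", y)


@dataclass(frozen=True)
class CO2Curve:
    """Cumulative CO2 production (grams), gravimetric, non-decreasing.

    A small tolerance (0.05 g) absorbs weighing noise in the
    monotonicity check.
    """

    times: np.ndarray
    co2_g: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.co2_g, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and co2_g must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("need at least two points")
        if np.any(np.diff(t) == 0):
            raise ValueError("duplicate times")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be increasing")
        if y[0] < 0:
            raise ValueError("cumulative CO2 cannot start negative")
        if np.any(np.diff(y) < -0.05):
            raise ValueError("cumulative CO2 must be non-decreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "co2_g", y)


@dataclass(frozen=True)
class LogisticFit:
    k: float
    n0: float
    r: float
    rss: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class KineticsSummary:
    """The five per-fermentation parameters; None marks 'not reached'."""

    t80: Optional[float]
    vmax: float
    lagtime: Optional[float]
    k: float
    r: float
    fit: LogisticFit


def logistic(t, k, n0, r):
    """Logistic growth n(t) = k / (1 + ((k - n0)/n0) exp(-r t))."""
    t = np.asarray(t, dtype=float)
    return k / (1.0 + ((k - n0) / n0) * np.exp(-r * t))


def fit_logistic(curve: GrowthCurve) -> LogisticFit:
    """Least-squares logistic fit of an OD curve.

    Initialization: k from the maximum OD, n0 from the first positive
    OD, r from the log-OD slope across the first two points above n0;
    bounded optimization keeps k > n0 > 0 and r > 0.  A flat curve is
    flagged as degenerate (no growth) rather than fitted.
    """
    t, y = curve.times, curve.od
    ymax = float(np.max(y))
    if ymax <= 0 or (ymax - float(np.min(y))) < 0.02 * max(ymax, 1e-12):
        return LogisticFit(
            k=ymax, n0=ymax, r=0.0, rss=float(np.sum((y - np.mean(y)) ** 2)),
            converged=False, message="degenerate: no measurable growth",
        )
    pos = y > 0
    n0_init = float(y[pos][0])
    above = np.flatnonzero(y > n0_init)
    if above.size >= 2:
        i, j = above[0], above[1]
        with np.errstate(divide="ignore"):
            r_init = (np.log(y[j]) - np.log(y[i])) / (t[j] - t[i])
        r_init = float(np.clip(r_init, 1e-3, 5.0))
    else:
        r_init = 0.1
    p0 = (ymax, max(n0_init, 1e-6), r_init)
    bounds = ([n0_init * 0.5 + 1e-9, 1e-9, 1e-6], [10 * ymax, ymax, 10.0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                logistic, t, y, p0=p0, bounds=bounds, maxfev=20000
            )
        k, n0, r = (float(v) for v in popt)
        rss = float(np.sum((logistic(t, k, n0, r) - y) ** 2))
        return LogisticFit(k=k, n0=n0, r=r, rss=rss, converged=True)
    except RuntimeError as exc:  # non-convergence is reported, not raised
        return LogisticFit(
            k=ymax, n0=n0_init, r=r_init, rss=float("nan"),
            converged=False, message=f"fit failed: {exc}",
        )


def _first_crossing(times: np.ndarray, values: np.ndarray, target: float) -> Optional[float]:
    """First time values reach target, linearly interpolated; None if never."""
    if values[0] >= target:
        return float(times[0])
    idx = np.flatnonzero(values >= target)
    if idx.size == 0:
        return None
    i = int(idx[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (target - v0) / (v1 - v0) * (t1 - t0))


def attenuation_time(
    curve: CO2Curve, medium: MediumSpec | float, fraction: float = 0.80
) -> Optional[float]:
    """Time to reach ``fraction`` of the theoretical CO2 maximum.

    ``medium`` may be a :class:`~pepferm.media.MediumSpec` (the
    theoretical maximum is computed from its sugars and volume) or the
    maximum itself in grams.  Returns None when the curve plateaus
    before the target — not all fermentations attenuate fully.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    max_g = theoretical_co2_max(medium) if isinstance(medium, MediumSpec) else float(medium)
    if max_g <= 0:
        raise ValueError("theoretical CO2 maximum must be positive")
    return _first_crossing(curve.times, curve.co2_g, fraction * max_g)


def max_co2_rate(curve: CO2Curve, smooth: bool = False) -> tuple[float, float]:
    """Maximum CO2 production rate (g/h) and the time it occurs.

    Rates are raw finite differences between consecutive samples,
    assigned to interval midpoints; ties resolve to the earliest
    interval.  ``smooth=True`` applies a centered 3-point moving
    average to the rates first (off by default: the coarse sampling
    grid makes raw differences the reproducible choice).
    """
    if curve.times.size < 3:
        raise ValueError("need at least 3 points for a rate profile")
    dt = np.diff(curve.times)
    rates = np.diff(curve.co2_g) / dt
    mids = curve.times[:-1] + dt / 2.0
    if smooth and rates.size >= 3:
        sm = rates.copy()
        sm[1:-1] = (rates[:-2] + rates[1:-1] + rates[2:]) / 3.0
        rates = sm
    i = int(np.argmax(rates))  # argmax returns the first maximum
    return float(max(rates[i], 0.0)), float(mids[i])


def lag_time(curve: CO2Curve, threshold: float = 1.0) -> Optional[float]:
    """Time to produce ``threshold`` grams of CO2 (default 1 g).

    Linearly interpolated between samples; None if never reached.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return _first_crossing(curve.times, curve.co2_g, threshold)


def summarize(
    growth: GrowthCurve, co2: CO2Curve, medium: MediumSpec | float
) -> KineticsSummary:
    """Assemble the five-parameter summary for one fermentation.

    The resulting rows (one per strain x medium) feed standard
    downstream statistics — ANOVA/Tukey and ordination — which are
    deliberately left to general-purpose tools.
    """
    fit = fit_logistic(growth)
    vmax, _ = max_co2_rate(co2)
    return KineticsSummary(
        t80=attenuation_time(co2, medium),
        vmax=vmax,
        lagtime=lag_time(co2),
        k=fit.k,
        r=fit.r,
        fit=fit,
    )
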