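"""Kinetic inference: initial rates, pseudo-first-order k2, reaction
orders from log-log plots, and Hammett linear free-energy regression.

All straight-line fits are ordinary least squares via
:func:`scipy.stats.linregress`; log-log and LFER math use base-10
logarithms, the convention of the Hammett literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

__all__ = [
    "RateFit",
    "OrderFit",
    "HammettResult",
    "HANSCH_SIGMA",
    "fit_initial_rate",
    "kobs_from_trace",
    "kobs_to_k2",
    "loglog_order",
    "hammett_fit",
]


@dataclass(frozen=True)
class RateFit:
    """An OLS line fit with the window of points it was fitted on."""

    slope: float
    intercept: float
    stderr_slope: float
    r_squared: float
    window: tuple[int, int]  # [start, stop) indices into the input series

    def __post_init__(self) -> None:
        if self.window[1] - self.window[0] < 2:
            raise ValueError("fit window must contain >= 2 points")
        if self.stderr_slope < 0:
            raise ValueError("stderr must be >= 0")


@dataclass(frozen=True)
class OrderFit:
    """A reaction order from a log10(rate) vs log10(conc) regression."""

    order: float
    stderr: float
    points: list[tuple[float, float]]  # (log10 conc, log10 rate)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("order fit needs >= 2 points")
        if not np.isfinite(self.order):
            raise ValueError("order is not finite")


@dataclass(frozen=True)
class HammettResult:
    """rho with standard error from log10(kX/kref) vs sigma."""

    rho: float
    stderr_rho: float
    intercept: float
    r_squared: float
    points: dict[str, tuple[float, float]]  # substituent -> (sigma, log10 ratio)

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("Hammett fit needs >= 3 substituents")


#: Standard Hansch sigma_para / sigma_meta substituent constants for the
#: aniline derivatives shipped with the tosylation study.  Fully
#: overridable: any {label: sigma} mapping containing the reference at 0.0
#: is accepted by :func:`hammett_fit`.
HANSCH_SIGMA: dict[str, float] = {
    "H": 0.0,
    "p-OMe": -0.27,
    "p-Me": -0.17,
    "m-Me": -0.07,
    "p-F": 0.06,
    "m-OMe": 0.12,
    "p-Cl": 0.23,
    "p-Br": 0.23,
}


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """slope, intercept, stderr_slope, r_squared."""
    res = linregress(x, y)
    # a perfect vertical spread of zero makes rvalue nan; treat as exact
    r2 = 1.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    return float(res.slope), float(res.intercept), stderr, r2


def _resolve_window(
    times: np.ndarray,
    values: np.ndarray,
    window: int | None,
    max_conversion: float | None,
) -> int:
    """Number of leading points to fit.

    The default window is all points up to ``window`` (the fixed datapoint
    budget of the acquisition schedule), further shortened to the points
    below ``max_conversion`` when the series is a conversion trace — the
    early-linearity guard for fast runs.  At least 2 points are always
    kept.
    """
    n = times.size
    stop = n if window is None else min(window, n)
    if max_conversion is not None:
        below = np.nonzero(values <= max_conversion)[0]
        if below.size >= 2:
            stop = min(stop, int(below[-1]) + 1)
    return max(stop, 2)


def fit_initial_rate(
    times: np.ndarray,
    values: np.ndarray,
    window: int | None = None,
    max_conversion: float | None = None,
) -> RateFit:
    """OLS slope of the early portion of a kinetic series.

    Parameters
    ----------
    times, values
        The series (minutes vs conversion fraction or concentration).
        Times must be strictly increasing.
    window
        Fit the first ``window`` points (default: all).  A window larger
        than the series is an error only when explicitly larger than the
        data would ever allow (< 2 points).
    max_conversion
        If given, drop trailing points above this conversion before
        fitting, protecting the linear-regime assumption.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.ndim != 1:
        raise ValueError("times and values must be equal-length 1-D arrays")
    if times.size < 2:
        raise ValueError("need >= 2 points for an initial-rate fit")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if window is not None and window > times.size:
        raise ValueError(f"window {window} larger than series of {times.size} points")
    stop = _resolve_window(times, values, window, max_conversion)
    slope, intercept, stderr, r2 = _ols(times[:stop], values[:stop])
    return RateFit(slope, intercept, stderr, r2, window=(0, stop))


def kobs_from_trace(
    times: np.ndarray,
    concentrations: np.ndarray,
    window: int | None = None,
) -> tuple[float, RateFit]:
    """Observed pseudo-first-order decay constant from a substrate trace.

    Fits the initial rate over the window and normalizes it by the mean
    substrate concentration over that same window:
    k_obs = -slope / mean([A]).  Evaluating the rate law at the window
    centroid rather than at [A]0 removes the leading-order truncation bias
    of the linear fit on an exponential decay, so moderately converted
    windows still return an essentially unbiased k_obs.
    """
    fit = fit_initial_rate(times, concentrations, window=window)
    mean_conc = float(np.mean(np.asarray(concentrations, dtype=float)[: fit.window[1]]))
    if mean_conc <= 0:
        raise ValueError("mean concentration over the window is not positive")
    return -fit.slope / mean_conc, fit


def kobs_to_k2(pairs: list[tuple[float, float]]) -> RateFit:
    """Second-order rate constant from k_obs vs excess-reagent concentration.

    Under pseudo-first-order conditions k_obs = k2 * [excess], so the OLS
    slope of k_obs against the excess concentration is k2
    (mM^-1 min^-1).  The intercept is reported, not forced to zero: a
    nonzero intercept is the diagnostic for a background reaction.
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 (concentration, k_obs) pairs")
    conc = np.array([c for c, _ in pairs], dtype=float)
    kobs = np.array([k for _, k in pairs], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("need >= 2 distinct excess concentrations")
    if np.any(kobs < 0):
        raise ValueError("k_obs values must be >= 0")
    slope, intercept, stderr, r2 = _ols(conc, kobs)
    return RateFit(slope, intercept, stderr, r2, window=(0, conc.size))


def loglog_order(pairs: list[tuple[float, float]]) -> OrderFit:
    """Reaction order as the slope of log10(rate) vs log10(concentration).

    Non-positive rates (possible after noisy near-zero fits) are dropped
    with a warning; at least 2 points must survive.
    """
    kept: list[tuple[float, float]] = []
    for conc, rate in pairs:
        if conc <= 0:
            raise ValueError(f"non-positive concentration {conc}")
        if rate <= 0:
            warnings.warn(
                f"dropping non-positive rate {rate} at {conc} mM from log-log fit",
                stacklevel=2,
            )
            continue
        kept.append((np.log10(conc), np.log10(rate)))
    if len(kept) < 2:
        raise ValueError("fewer than 2 positive-rate points for log-log fit")
    x = np.array([p[0] for p in kept])
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct concentrations")
    y = np.array([p[1] for p in kept])
    slope, _, stderr, _ = _ols(x, y)
    return OrderFit(order=slope, stderr=stderr, points=kept)


def hammett_fit(
    rates: dict[str, float],
    sigmas: dict[str, float],
    reference: str = "H",
) -> HammettResult:
    """Hammett rho from substituent rates at fixed conditions.

    Regresses log10(k_X / k_ref) against the tabulated substituent
    constants sigma; the slope rho reports charge development in the
    transition state (negative rho: electron-donating substituents
    accelerate).  The reference substituent enters at (sigma_ref, 0).
    """
    if reference not in rates:
        raise ValueError(f"reference substituent {reference!r} has no measured rate")
    if reference not in sigmas:
        raise ValueError(f"reference substituent {reference!r} has no sigma value")
    missing = sorted(set(rates) - set(sigmas))
    if missing:
        raise ValueError(f"no sigma constant for substituents: {missing}")
    if len(rates) < 3:
        raise ValueError("Hammett fit needs >= 3 substituents")
    k_ref = rates[reference]
    if k_ref <= 0:
        raise ValueError("reference rate must be > 0")
    points: dict[str, tuple[float, float]] = {}
    for label, k in rates.items():
        if k <= 0:
            raise ValueError(f"rate for {label!r} must be > 0")
        points[label] = (float(sigmas[label]), float(np.log10(k / k_ref)))
    x = np.array([p[0] for p in points.values()])
    y = np.array([p[1] for p in points.values()])
    slope, intercept, stderr, r2 = _ols(x, y)
    return HammettResult(
        rho=slope, stderr_rho=stderr, intercept=intercept, r_squared=r2, points=points
    )
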