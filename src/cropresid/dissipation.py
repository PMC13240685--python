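"""First-order dissipation kinetics.

Residue decay in plant tissue is modelled as single first-order kinetics,

    C(t) = C0 * exp(-k t),        t_1/2 = ln 2 / k,

with C in mg/kg fresh weight, t in days after the last application and k in
day⁻¹. Two estimators are provided: nonlinear least squares on the original
scale (default, matching how dissipation studies report fits) and ordinary
least squares on log-transformed concentrations. Goodness of fit is always
reported on the original (untransformed) scale so the two methods are
comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .datamodel import ResidueSeries
from .errors import (FitConvergenceError, InsufficientDataError,
                     NonDissipatingError, ValidationError)

__all__ = ["DissipationFit", "fit_first_order", "half_life", "predict_residue"]

_MAX_ITER = 10_000
_TOL = 1e-10


@dataclass(frozen=True)
class DissipationFit:
    """Fitted first-order dissipation parameters for one residue series.

    ``t_half`` is derived as ln2/k; ``r2_fit`` is the coefficient of
    determination of the fitted curve against the observations on the
    original concentration scale (<= 1, may be negative for a bad fit).
    """

    pesticide: str
    c0: float          # mg/kg
    k: float           # per day
    t_half: float      # days
    r2_fit: float
    n_points: int
    method_label: str  # "nonlinear" | "loglinear"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise NonDissipatingError(
                f"{self.pesticide!r}: rate constant must be > 0, got {self.k}")
        if self.c0 <= 0:
            raise ValidationError(f"c0 must be > 0, got {self.c0}")
        if self.n_points < 3:
            raise InsufficientDataError("fit needs at least 3 points")
        if not math.isclose(self.t_half, math.log(2.0) / self.k,
                            rel_tol=0, abs_tol=0):
            raise ValidationError("t_half must equal ln(2)/k exactly")


def half_life(k: float) -> float:
    """Half-life ln(2)/k in days for a first-order rate constant k (day⁻¹)."""
    if k <= 0:
        raise NonDissipatingError(f"half-life undefined for k <= 0 (got {k})")
    return math.log(2.0) / k


def predict_residue(fit: DissipationFit, times) -> np.ndarray:
    """Evaluate C0·exp(−k t) at the requested times (days, >= 0)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValidationError("prediction times must be >= 0")
    return fit.c0 * np.exp(-fit.k * t)


def _pooled_arrays(series: ResidueSeries,
                   average_replicates: bool) -> tuple[np.ndarray, np.ndarray]:
    t = np.array(series.times(), dtype=float)
    c = np.array(series.concentrations(), dtype=float)
    if average_replicates:
        order = np.argsort(t, kind="stable")
        t, c = t[order], c[order]
        uniq, inverse = np.unique(t, return_inverse=True)
        means = np.zeros_like(uniq)
        counts = np.zeros_like(uniq)
        np.add.at(means, inverse, c)
        np.add.at(counts, inverse, 1.0)
        return uniq, means / counts
    return t, c


def _loglinear_estimate(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """OLS of log C on t over the positive concentrations → (c0, k)."""
    mask = c > 0
    if np.count_nonzero(mask) < 2 or len(np.unique(t[mask])) < 2:
        raise InsufficientDataError(
            "loglinear fit needs >= 2 positive concentrations at distinct times")
    slope, intercept = np.polyfit(t[mask], np.log(c[mask]), 1)
    return float(np.exp(intercept)), float(-slope)


def _r2_original_scale(c: np.ndarray, fitted: np.ndarray) -> float:
    sse = float(np.sum((c - fitted) ** 2))
    sst = float(np.sum((c - c.mean()) ** 2))
    if sst == 0.0:
        return 1.0 if sse == 0.0 else float("-inf")
    return 1.0 - sse / sst


def fit_first_order(series: ResidueSeries, method: str = "nonlinear",
                    average_replicates: bool = False) -> DissipationFit:
    """Fit C(t) = C0·exp(−k t) to a residue series.

    Parameters
    ----------
    series : ResidueSeries
        Observations; replicates are pooled into the objective with equal
        weight unless ``average_replicates`` averages them per timepoint
        first.
    method : {"nonlinear", "loglinear"}
        ``nonlinear`` (default) minimises Σ(Cᵢ − C0·e^(−k tᵢ))² directly,
        initialised from the earliest observation (C0) and a log-linear
        regression (k). ``loglinear`` regresses log Cᵢ on tᵢ, excluding
        zero concentrations (log undefined); zeros are retained by the
        nonlinear objective.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 distinct timepoints, or fewer than 2 nonzero
        concentrations.
    NonDissipatingError
        The optimal rate constant is <= 0 (series does not decay); never
        clamped.
    """
    series = series.sorted_by_time()
    if series.n_distinct_times() < 3:
        raise InsufficientDataError(
            f"{series.pesticide!r}: need >= 3 distinct timepoints, "
            f"got {series.n_distinct_times()}")
    t, c = _pooled_arrays(series, average_replicates)
    if np.count_nonzero(c > 0) < 2:
        raise InsufficientDataError(
            f"{series.pesticide!r}: need >= 2 nonzero concentrations")

    if method == "loglinear":
        c0, k = _loglinear_estimate(t, c)
        if k <= 0:
            raise NonDissipatingError(
                f"{series.pesticide!r}: log-linear slope gives k={k:.4g} <= 0")
    elif method == "nonlinear":
        try:
            c0_init = float(c[t == t.min()].mean())
            if c0_init <= 0:
                c0_init = float(c[c > 0].max())
            try:
                _, k_init = _loglinear_estimate(t, c)
                if k_init <= 0:
                    k_init = 1e-3
            except InsufficientDataError:
                k_init = 1e-3
            popt, _ = curve_fit(
                lambda tt, c0_, k_: c0_ * np.exp(-k_ * tt),
                t, c, p0=[c0_init, k_init],
                maxfev=_MAX_ITER, ftol=_TOL, xtol=_TOL)
        except RuntimeError as exc:
            raise FitConvergenceError(
                f"{series.pesticide!r}: nonlinear fit did not converge: {exc}"
            ) from exc
        c0, k = float(popt[0]), float(popt[1])
        if k <= 0 or c0 <= 0:
            raise NonDissipatingError(
                f"{series.pesticide!r}: optimal fit is non-dissipating "
                f"(c0={c0:.4g}, k={k:.4g})")
    else:
        raise ValueError(f"unknown method {method!r}")

    fitted = c0 * np.exp(-k * t)
    return DissipationFit(
        pesticide=series.pesticide, c0=c0, k=k, t_half=math.log(2.0) / k,
        r2_fit=_r2_original_scale(c, fitted), n_points=int(len(t)),
        method_label=method)
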