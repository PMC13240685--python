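"""Model-validation statistics for measured-vs-predicted residue series.

Four statistics are computed over a time-aligned pair of measured (Aᵢ) and
predicted (Fᵢ) concentrations:

* R² = 1 − SSE/SST, with SSE = Σ(Aᵢ−Fᵢ)² and SST = Σ(Aᵢ−Ā)²; not clamped
  below, so a prediction worse than the measured mean goes negative,
* MAE = (1/n) Σ|Aᵢ−Fᵢ| (mg/kg),
* RRMSE = 100 · RMSE / quadratic mean of the predictions (%), a
  scale-invariant relative error (an alternative normalisation dividing by
  the *total* ΣFᵢ² inside the radical is available),
* RMSLE = sqrt((1/n) Σ(ln(1+Aᵢ) − ln(1+Fᵢ))²), natural log, robust to the
  several-orders-of-magnitude spread of residue data.

A prediction is additionally screened for regulatory *reliability*: its MAE
must stay strictly below the commodity's maximum residue limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError, ValidationError

__all__ = ["PairedSeries", "ValidationReport", "r_squared", "mae", "rrmse",
           "rmsle", "evaluate_pair"]


@dataclass(frozen=True)
class PairedSeries:
    """Time-aligned measured (a) and predicted (f) concentrations, mg/kg."""

    a: np.ndarray
    f: np.ndarray
    times: np.ndarray | None = None
    pesticide: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "f", np.asarray(self.f, dtype=float))
        if self.a.shape != self.f.shape or self.a.ndim != 1:
            raise ValidationError("a and f must be 1-D arrays of equal length")
        if len(self.a) < 2:
            raise ValidationError("paired series needs n >= 2")
        if np.any(self.a < 0) or np.any(self.f < 0):
            raise ValidationError("concentrations must be >= 0")
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            if t.shape != self.a.shape:
                raise ValidationError("times must align with the series")
            object.__setattr__(self, "times", t)

    @property
    def n(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class ValidationReport:
    """Bundle of the four statistics plus the MRL reliability screen."""

    pesticide: str
    r2: float
    mae: float       # mg/kg
    rrmse: float     # percent
    rmsle: float
    n: int
    mrl_reliable: bool


def r_squared(pair: PairedSeries) -> float:
    """Coefficient of determination 1 − SSE/SST; may be negative."""
    sse = float(np.sum((pair.a - pair.f) ** 2))
    sst = float(np.sum((pair.a - pair.a.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedStatisticError(
            "R² undefined: measured series is constant (SST = 0)")
    return 1.0 - sse / sst


def mae(pair: PairedSeries) -> float:
    """Mean absolute error (mg/kg)."""
    return float(np.mean(np.abs(pair.a - pair.f)))


def rrmse(pair: PairedSeries, normalization: str = "quadratic-mean") -> float:
    """Relative root-mean-square error, percent.

    ``quadratic-mean`` (default): 100 · sqrt(Σ(Aᵢ−Fᵢ)²/n) / sqrt(ΣFᵢ²/n),
    invariant to rescaling both series. ``total`` divides by the plain sum
    ΣFᵢ² inside the radical instead (the literal alternative reading; its
    value shrinks with n and is kept only for comparison).
    """
    ss_pred = float(np.sum(pair.f ** 2))
    if ss_pred == 0.0:
        raise UndefinedStatisticError(
            "RRMSE undefined: all predictions are zero")
    sse = float(np.sum((pair.a - pair.f) ** 2))
    if normalization == "quadratic-mean":
        return 100.0 * math.sqrt(sse / pair.n) / math.sqrt(ss_pred / pair.n)
    if normalization == "total":
        return 100.0 * math.sqrt(sse / (pair.n * ss_pred))
    raise ValueError(f"unknown normalization {normalization!r}")


def rmsle(pair: PairedSeries) -> float:
    """Root mean squared logarithmic error, natural log on 1 + x."""
    d = np.log1p(pair.a) - np.log1p(pair.f)
    return float(np.sqrt(np.mean(d ** 2)))


def evaluate_pair(pair: PairedSeries, mrl: float) -> ValidationReport:
    """All four statistics plus the MRL screen (reliable iff MAE < MRL,
    strict inequality)."""
    if mrl <= 0:
        raise ValidationError(f"MRL must be > 0, got {mrl}")
    mae_value = mae(pair)
    return ValidationReport(
        pesticide=pair.pesticide,
        r2=r_squared(pair),
        mae=mae_value,
        rrmse=rrmse(pair),
        rmsle=rmsle(pair),
        n=pair.n,
        mrl_reliable=bool(mae_value < mrl),
    )
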