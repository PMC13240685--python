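"""Dietary risk assessment: EDI, hazard quotients and pre-harvest intervals.

For a residue concentration C (mg/kg) in the commodity, a consumer eating
``daily_intake`` grams per day at ``body_weight`` kg receives an estimated
daily intake

    EDI = C · (daily_intake / 1000) / body_weight     [mg/kg bw/day]

which is compared to the most conservative (lowest) acceptable daily intake
across regulatory agencies as a hazard quotient

    HQ = EDI / ADI × 100                              [percent].

HQ < 100% is the conventional negligible-chronic-risk bound; a stricter
screening threshold (default 10%) drives the pre-harvest-interval
recommendation: the earliest evaluated day after the last application on
which HQ falls below the threshold.

The default consumption profile (26.4 g spinach/day, 60 kg body weight) is
a per-capita leafy-vegetable figure typical of Korean dietary surveys; both
numbers are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import PesticideProperties
from .errors import ConfigurationError, ValidationError
from .simulator import SimulationResult, residue_at_day

__all__ = ["ConsumptionProfile", "RiskRecord", "select_lowest_adi",
           "compute_edi", "compute_hq", "hq_timeline", "preharvest_interval",
           "NOT_REACHED", "audit_risk_table", "risk_table"]

#: Sentinel returned by :func:`preharvest_interval` when no evaluated day
#: meets the threshold within the horizon.
NOT_REACHED = None

DEFAULT_DAY_GRID = (0.0, 3.0, 7.0, 14.0)


@dataclass(frozen=True)
class ConsumptionProfile:
    """Commodity consumption (g/day) and consumer body weight (kg)."""

    daily_intake: float = 26.4
    body_weight: float = 60.0

    def __post_init__(self) -> None:
        if self.daily_intake <= 0 or self.body_weight <= 0:
            raise ValidationError(
                "daily_intake and body_weight must both be > 0")

    @property
    def intake_factor(self) -> float:
        """kg commodity per kg body weight per day."""
        return self.daily_intake / 1000.0 / self.body_weight


@dataclass(frozen=True)
class RiskRecord:
    """One pesticide × day entry of a risk table."""

    pesticide: str
    day: float               # days after last application
    concentration: float     # mg/kg
    edi: float               # mg/kg bw/day
    adi: float               # mg/kg bw/day
    adi_agency: str
    hq: float                # percent

    def __post_init__(self) -> None:
        for attr in ("concentration", "edi", "adi", "hq"):
            if getattr(self, attr) < 0:
                raise ValidationError(f"{attr} must be >= 0")


def select_lowest_adi(adi_by_agency: Mapping[str, float]) -> tuple[float, str]:
    """Most conservative ADI across agencies, with its agency label.

    Ties are broken by lexicographic agency label so the choice is
    deterministic.
    """
    if not adi_by_agency:
        raise ConfigurationError("no ADI values available")
    agency = min(sorted(adi_by_agency), key=lambda a: adi_by_agency[a])
    return float(adi_by_agency[agency]), agency


def compute_edi(concentration: float,
                profile: ConsumptionProfile | None = None) -> float:
    """Estimated daily intake, mg/kg bw/day."""
    if concentration < 0:
        raise ValidationError("concentration must be >= 0")
    profile = profile or ConsumptionProfile()
    return concentration * profile.intake_factor


def compute_hq(edi: float, adi: float) -> float:
    """Hazard quotient EDI/ADI × 100, percent."""
    if adi <= 0:
        raise ValidationError(f"ADI must be > 0, got {adi}")
    return 100.0 * edi / adi


ResidueSource = "SimulationResult | Mapping[float, float] | Callable[[float], float]"


def _residue_lookup(source, day: float) -> float:
    if isinstance(source, SimulationResult):
        return residue_at_day(source, day)
    if isinstance(source, Mapping):
        if day not in source:
            raise ValidationError(f"no residue value for day {day}")
        return float(source[day])
    if callable(source):
        return float(source(day))
    raise TypeError(f"unsupported residue source {type(source).__name__}")


def hq_timeline(residue_source, pesticide: PesticideProperties,
                days: Sequence[float] = DEFAULT_DAY_GRID,
                profile: ConsumptionProfile | None = None) -> list[RiskRecord]:
    """Risk records over a day grid using the compound's lowest ADI.

    ``residue_source`` may be a :class:`SimulationResult` (interpolated), a
    mapping day → concentration, or a callable.
    """
    profile = profile or ConsumptionProfile()
    adi, agency = select_lowest_adi(pesticide.adi_by_agency)
    records = []
    for day in sorted(days):
        conc = _residue_lookup(residue_source, day)
        edi = compute_edi(conc, profile)
        records.append(RiskRecord(
            pesticide=pesticide.name, day=float(day), concentration=conc,
            edi=edi, adi=adi, adi_agency=agency, hq=compute_hq(edi, adi)))
    return records


def preharvest_interval(records: Sequence[RiskRecord],
                        threshold: float = 10.0):
    """Smallest evaluated day with HQ strictly below ``threshold`` percent.

    Returns :data:`NOT_REACHED` (None) if no evaluated day qualifies. Only
    the evaluated grid is examined — no interpolation between days.
    """
    if not records:
        raise ValidationError("no risk records supplied")
    for rec in sorted(records, key=lambda r: r.day):
        if rec.hq < threshold:
            return rec.day
    return NOT_REACHED


def risk_table(records: Sequence[RiskRecord]) -> pd.DataFrame:
    """Tidy risk table (one row per pesticide × day)."""
    return pd.DataFrame([{
        "pesticide": r.pesticide, "adi": r.adi, "adi_agency": r.adi_agency,
        "day": r.day, "concentration": r.concentration, "edi": r.edi,
        "hq": r.hq} for r in records])


def audit_risk_table(table: pd.DataFrame,
                     profile: ConsumptionProfile | None = None,
                     rtol: float = 0.005) -> pd.DataFrame:
    """Recompute HQ from concentration and ADI and flag inconsistent rows.

    ``table`` needs columns ``pesticide, day, concentration, adi,
    hq_printed``. Published risk tables occasionally carry row-shifted or
    mistranscribed ADIs; recomputing HQ = C · intake_factor / ADI × 100 and
    comparing against the printed value (relative tolerance ``rtol``)
    localises them. Returns the table with ``hq_recomputed``, ``rel_err``
    and ``consistent`` columns added.
    """
    profile = profile or ConsumptionProfile()
    out = table.copy()
    out["hq_recomputed"] = [
        compute_hq(compute_edi(c, profile), adi)
        for c, adi in zip(out["concentration"], out["adi"])]
    printed = out["hq_printed"].astype(float)
    out["rel_err"] = np.where(
        printed > 0,
        np.abs(out["hq_recomputed"] - printed) / printed,
        np.abs(out["hq_recomputed"] - printed))
    out["consistent"] = out["rel_err"] <= rtol
    return out
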