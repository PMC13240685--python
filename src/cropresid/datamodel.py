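"""Shared domain types for the residue-analysis pipeline.

Unit conventions are fixed package-wide and never inferred:

* time — days; the origin is the **last** application, so application events
  before the final spray carry negative times,
* residue concentration — mg/kg fresh weight of edible tissue,
* applied mass — kg active ingredient per m² ground area, per application,
* ADI — mg per kg body weight per day, keyed by the regulatory agency label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = [
    "PesticideProperties",
    "CropParameters",
    "ApplicationEvent",
    "ApplicationSchedule",
    "ResidueSample",
    "ResidueSeries",
]

_FRACTION_TOL = 1e-9


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class PesticideProperties:
    """Physicochemical, application and regulatory constants for one compound.

    Parameters
    ----------
    name : str
        Compound identifier, e.g. ``"pencycuron"``.
    molecular_weight : float
        g/mol.
    kow : float
        Octanol–water partition coefficient (dimensionless); lipophilicity
        proxy governing tissue partitioning and translocation.
    mrl : float
        Maximum residue limit, mg/kg, for the commodity in ``mrl_commodity``.
    t_half_plant : float
        First-order dissipation half-life in the edible plant tissue, days.
    t_half_soil : float
        First-order degradation half-life in soil, days.
    m_applied : float
        Active-ingredient mass per application, kg/m².
    adi_by_agency : dict[str, float]
        Acceptable daily intake (mg/kg bw/day) keyed by agency label
        ("Korea", "CODEX", "Japan", "USA", "Europe", ...). Free strings;
        unknown agencies are preserved.
    role_label : str
        ``"fungicide"`` or ``"insecticide"`` (drives the spray count of the
        default schedules).
    mrl_commodity : str
        Commodity the MRL refers to, e.g. ``"spinach"`` or
        ``"leafy vegetable"``.
    """

    name: str
    molecular_weight: float
    kow: float
    mrl: float
    t_half_plant: float
    t_half_soil: float
    m_applied: float
    adi_by_agency: dict[str, float] = field(default_factory=dict)
    role_label: str = "insecticide"
    mrl_commodity: str = "spinach"

    def __post_init__(self) -> None:
        for attr in ("molecular_weight", "kow", "mrl", "t_half_plant",
                     "t_half_soil", "m_applied"):
            value = getattr(self, attr)
            _require(math.isfinite(value) and value > 0,
                     f"{self.name!r}: {attr} must be finite and > 0, got {value}")
        for agency, adi in self.adi_by_agency.items():
            _require(adi > 0,
                     f"{self.name!r}: ADI for {agency!r} must be > 0, got {adi}")
        _require(self.role_label in ("fungicide", "insecticide"),
                 f"{self.name!r}: role_label must be 'fungicide' or "
                 f"'insecticide', got {self.role_label!r}")

    @property
    def log_kow(self) -> float:
        """log10 Kow."""
        return math.log10(self.kow)

    @property
    def k_plant(self) -> float:
        """First-order plant dissipation rate constant, per day."""
        return math.log(2.0) / self.t_half_plant

    @property
    def k_soil(self) -> float:
        """First-order soil degradation rate constant, per day."""
        return math.log(2.0) / self.t_half_soil


@dataclass(frozen=True)
class CropParameters:
    """Crop- and soil-specific inputs for the compartment simulator.

    Fields mirror a standard crop parameterisation sheet for a leafy
    vegetable: soil descriptors, fresh-weight yield, biomass partitioning
    between root/stem/leaf, and leaf area index (LAI) at the start of growth,
    at application and at harvest.
    """

    soil_organic_carbon: float   # kg/kg
    soil_ph: float               # dimensionless
    soil_depth: float            # m
    yield_fresh: float           # kg/m², fresh weight at harvest
    root_fraction: float         # kg_root / kg_aerial
    stem_fraction: float         # kg_stem / kg_aerial
    leaf_fraction: float         # kg_leaf / kg_aerial
    lai_start: float             # m²/m²
    lai_harvest: float           # m²/m²
    lai_at_application: float    # m²/m²
    leaf_cover_harvest: float    # treated as dimensionless, see docs

    def __post_init__(self) -> None:
        _require(self.yield_fresh > 0, "yield_fresh must be > 0")
        for attr in ("root_fraction", "stem_fraction", "leaf_fraction"):
            value = getattr(self, attr)
            _require(0.0 <= value <= 1.0, f"{attr} must be in [0, 1], got {value}")
        _require(abs(self.stem_fraction + self.leaf_fraction - 1.0) <= _FRACTION_TOL,
                 "stem_fraction + leaf_fraction must equal 1 "
                 f"(got {self.stem_fraction} + {self.leaf_fraction})")
        for attr in ("lai_start", "lai_harvest", "lai_at_application",
                     "leaf_cover_harvest"):
            _require(getattr(self, attr) >= 0, f"{attr} must be >= 0")
        _require(self.soil_depth > 0, "soil_depth must be > 0")


@dataclass(frozen=True)
class ApplicationEvent:
    """One spray event.

    ``time`` is in days relative to the last application (the last event of a
    schedule is at 0, earlier ones negative). ``dilution_volume`` (L per
    10 a) is spray-solution metadata and plays no role in mass computations.
    """

    time: float
    dose: float                      # kg active ingredient / m²
    dilution_volume: float | None = None

    def __post_init__(self) -> None:
        _require(self.dose > 0, f"dose must be > 0, got {self.dose}")


@dataclass(frozen=True)
class ApplicationSchedule:
    """Ordered spray schedule; times strictly increasing."""

    events: tuple[ApplicationEvent, ...]

    def __post_init__(self) -> None:
        _require(len(self.events) >= 1, "schedule needs at least one event")
        times = [e.time for e in self.events]
        _require(all(b > a for a, b in zip(times, times[1:])),
                 f"event times must be strictly increasing, got {times}")

    @property
    def n_applications(self) -> int:
        return len(self.events)

    @property
    def last_time(self) -> float:
        return self.events[-1].time

    @property
    def first_time(self) -> float:
        return self.events[0].time

    @classmethod
    def from_interval(cls, n_applications: int, dose: float,
                      interval_days: float = 7.0,
                      dilution_volume: float | None = None) -> "ApplicationSchedule":
        """Build an evenly spaced schedule ending at day 0.

        ``n_applications`` sprays separated by ``interval_days``, each at
        ``dose`` kg/m²; the final spray is at time 0 by the package's
        days-after-last-application convention.
        """
        _require(n_applications >= 1, "n_applications must be >= 1")
        _require(interval_days > 0, "interval_days must be > 0")
        events = tuple(
            ApplicationEvent(time=-(n_applications - 1 - i) * interval_days,
                             dose=dose, dilution_volume=dilution_volume)
            for i in range(n_applications)
        )
        return cls(events=events)


@dataclass(frozen=True)
class ResidueSample:
    """A single residue determination in edible tissue."""

    time: float              # days after last application, >= 0
    concentration: float     # mg/kg fresh weight, >= 0
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        _require(self.time >= 0, f"sample time must be >= 0, got {self.time}")
        _require(self.concentration >= 0,
                 f"concentration must be >= 0, got {self.concentration}")


@dataclass(frozen=True)
class ResidueSeries:
    """Residue time series for one pesticide (measured or simulated).

    Replicates are kept as individual samples; averaging is a downstream
    choice, never done at construction or parse time.
    """

    pesticide: str
    samples: tuple[ResidueSample, ...]

    def __post_init__(self) -> None:
        _require(len(self.samples) >= 1, "series needs at least one sample")

    def times(self) -> list[float]:
        return [s.time for s in self.samples]

    def concentrations(self) -> list[float]:
        return [s.concentration for s in self.samples]

    def n_distinct_times(self) -> int:
        return len({s.time for s in self.samples})

    def sorted_by_time(self) -> "ResidueSeries":
        return ResidueSeries(
            pesticide=self.pesticide,
            samples=tuple(sorted(self.samples,
                                 key=lambda s: (s.time, s.replicate_id))),
        )
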