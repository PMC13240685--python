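"""Compartmental residue simulator with multi-application superposition.

The simulator tracks pesticide mass (kg/m² ground area) in six compartments —
spray deposit on the leaf surface, leaf tissue, stem, root, soil and air —
plus a cumulative-degraded pool, under a **linear, constant-coefficient
first-order transfer system**:

* at each spray event the dose is split by Beer–Lambert canopy interception,
  f_int = 1 − exp(−κ·LAI), between the leaf-surface deposit and the soil;
* the deposit loses mass to leaf tissue (cuticular penetration) and to air
  (wash-off/volatilisation);
* leaf ↔ stem ↔ root translocation rates are scaled by a decreasing logistic
  function of log10 Kow — strongly lipophilic compounds barely translocate;
* every compartment degrades in place; plant-side degradation is calibrated
  so the **edible aggregate** (deposit + leaf + stem) decays at exactly
  ln2 / t_half_plant, and soil at ln2 / t_half_soil (wash-off and stem→root
  export are debited from the in-place degradation of their source
  compartments, see docs/methods.md).

Because the system is linear, the residue after n applications is the sum of
n single-application solutions — the superposition premise used throughout
the risk assessment.

Edible residue (mg/kg fresh weight) is the aerial mass
(deposit + leaf + stem) divided by the fresh yield, × 1e6 (kg → mg).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .datamodel import ApplicationSchedule, CropParameters, PesticideProperties
from .errors import (AlignmentError, ConfigurationError, StabilityError,
                     ValidationError)

__all__ = [
    "COMPARTMENTS", "SimulatorConfig", "TransferRates", "CompartmentState",
    "SimulationResult", "interception_fraction", "apply_event",
    "simulate_trajectories", "superpose_applications", "residue_at_day",
]

COMPARTMENTS = ("leaf_deposit", "leaf", "stem", "root", "soil", "air")
_IDX = {name: i for i, name in enumerate(COMPARTMENTS)}
_N = len(COMPARTMENTS)
_EDIBLE = [_IDX["leaf_deposit"], _IDX["leaf"], _IDX["stem"]]

_MASS_BALANCE_RTOL = 1e-9


@dataclass(frozen=True)
class SimulatorConfig:
    """Tunable process rates (day⁻¹ unless noted) and numerical options.

    ``compensate_calibration`` keeps the edible-tissue aggregate on the
    measured plant half-life by debiting wash-off (deposit) and stem→root
    export (stem) from those compartments' in-place degradation; disable to
    interpret every rate literally.
    """

    kappa: float = 0.4                    # canopy extinction coefficient
    k_penetration: float = 0.1            # deposit → leaf tissue
    k_washoff: float = 0.1                # deposit → air (wash-off/volatilisation)
    k_leaf_stem: float = 0.05             # phloem export, scaled by Kow logistic
    k_stem_leaf: float = 0.02
    k_stem_root: float = 0.02
    k_root_stem: float = 0.0              # return flow, off by default
    k_soil_uptake: float = 0.0            # soil → root, off by default
    k_air_loss: float = 2.0               # advection/photolysis sink
    kow_logistic_mid: float = 3.0         # log10 Kow at half translocation
    kow_logistic_width: float = 0.8
    compensate_calibration: bool = True
    step: float = 0.01                    # integration step, days
    method: str = "rk4"                   # "rk4" | "expm"
    strict: bool = False                  # escalate stability warning to error


def translocation_factor(log_kow: float, config: SimulatorConfig) -> float:
    """Decreasing logistic in log10 Kow, in (0, 1): lipophilic compounds
    partition into cuticle/membranes and translocate less."""
    z = (log_kow - config.kow_logistic_mid) / config.kow_logistic_width
    return 1.0 / (1.0 + math.exp(z))


@dataclass(frozen=True)
class TransferRates:
    """Fully resolved first-order rate constants (day⁻¹) for one compound.

    ``transfer[src → dst]`` entries are conservative flows; ``deg_*`` are
    losses to the cumulative-degraded pool.
    """

    k_deposit_leaf: float
    k_deposit_air: float
    k_leaf_stem: float
    k_stem_leaf: float
    k_stem_root: float
    k_root_stem: float
    k_soil_root: float
    deg_deposit: float
    deg_leaf: float
    deg_stem: float
    deg_root: float
    deg_soil: float
    deg_air: float

    @classmethod
    def from_properties(cls, pesticide: PesticideProperties,
                        config: SimulatorConfig | None = None) -> "TransferRates":
        """Resolve rates for a compound from its half-lives and Kow.

        In-place degradation of every plant compartment starts from
        k_plant = ln2/t_half_plant; with ``compensate_calibration`` the
        deposit's wash-off and the stem's root export are subtracted from
        their in-place degradation (floored at 0) so the edible aggregate
        decays at exactly k_plant when root→stem return is off.
        """
        config = config or SimulatorConfig()
        k_plant = pesticide.k_plant
        k_soil = pesticide.k_soil
        f = translocation_factor(pesticide.log_kow, config)
        k_washoff = config.k_washoff
        k_stem_root = config.k_stem_root * f
        if config.compensate_calibration:
            deg_deposit = max(k_plant - k_washoff, 0.0)
            deg_stem = max(k_plant - k_stem_root, 0.0)
            deg_soil = max(k_soil - config.k_soil_uptake, 0.0)
        else:
            deg_deposit = k_plant
            deg_stem = k_plant
            deg_soil = k_soil
        return cls(
            k_deposit_leaf=config.k_penetration,
            k_deposit_air=k_washoff,
            k_leaf_stem=config.k_leaf_stem * f,
            k_stem_leaf=config.k_stem_leaf * f,
            k_stem_root=k_stem_root,
            k_root_stem=config.k_root_stem * f,
            k_soil_root=config.k_soil_uptake,
            deg_deposit=deg_deposit,
            deg_leaf=k_plant,
            deg_stem=deg_stem,
            deg_root=k_plant,
            deg_soil=deg_soil,
            deg_air=config.k_air_loss,
        )

    @classmethod
    def decay_only(cls, pesticide: PesticideProperties,
                   k_air_loss: float = 2.0) -> "TransferRates":
        """All inter-compartment transfers disabled; pure in-place decay at
        ln2/t_half_plant (plant side) and ln2/t_half_soil (soil)."""
        k_plant = pesticide.k_plant
        return cls(k_deposit_leaf=0.0, k_deposit_air=0.0, k_leaf_stem=0.0,
                   k_stem_leaf=0.0, k_stem_root=0.0, k_root_stem=0.0,
                   k_soil_root=0.0, deg_deposit=k_plant, deg_leaf=k_plant,
                   deg_stem=k_plant, deg_root=k_plant,
                   deg_soil=pesticide.k_soil, deg_air=k_air_loss)

    def matrix(self) -> np.ndarray:
        """(7×7) generator of the augmented linear system d/dt [m; degraded].

        Columns sum to zero exactly, so any consistent one-step method
        conserves total mass to round-off.
        """
        A = np.zeros((_N + 1, _N + 1))
        flows = [
            ("leaf_deposit", "leaf", self.k_deposit_leaf),
            ("leaf_deposit", "air", self.k_deposit_air),
            ("leaf", "stem", self.k_leaf_stem),
            ("stem", "leaf", self.k_stem_leaf),
            ("stem", "root", self.k_stem_root),
            ("root", "stem", self.k_root_stem),
            ("soil", "root", self.k_soil_root),
        ]
        for src, dst, rate in flows:
            A[_IDX[dst], _IDX[src]] += rate
            A[_IDX[src], _IDX[src]] -= rate
        deg = {"leaf_deposit": self.deg_deposit, "leaf": self.deg_leaf,
               "stem": self.deg_stem, "root": self.deg_root,
               "soil": self.deg_soil, "air": self.deg_air}
        for name, rate in deg.items():
            A[_N, _IDX[name]] += rate
            A[_IDX[name], _IDX[name]] -= rate
        return A


@dataclass(frozen=True)
class CompartmentState:
    """Mass (kg/m²) in each compartment at one time, plus the cumulative
    degraded pool; total applied mass is conserved."""

    masses: dict[str, float]
    cumulative_degraded: float
    time: float

    def total(self) -> float:
        return sum(self.masses.values()) + self.cumulative_degraded

    def check_mass_balance(self, total_applied: float,
                           rtol: float = _MASS_BALANCE_RTOL) -> None:
        if total_applied == 0:
            ok = abs(self.total()) <= rtol
        else:
            ok = abs(self.total() - total_applied) <= rtol * total_applied
        if not ok:
            raise ValidationError(
                f"mass balance violated at t={self.time}: "
                f"{self.total()} vs applied {total_applied}")


def interception_fraction(lai: float, kappa: float = 0.4) -> float:
    """Beer–Lambert canopy interception fraction 1 − exp(−κ·LAI)."""
    if lai < 0:
        raise ValidationError(f"LAI must be >= 0, got {lai}")
    return 1.0 - math.exp(-kappa * lai)


def apply_event(state: CompartmentState, dose: float, crop: CropParameters,
                kappa: float = 0.4) -> CompartmentState:
    """Add one spray dose to a state: the intercepted fraction lands on the
    leaf-surface deposit, the rest reaches the soil. Mass-conserving."""
    if dose <= 0:
        raise ValidationError(f"dose must be > 0, got {dose}")
    f_int = interception_fraction(crop.lai_at_application, kappa)
    masses = dict(state.masses)
    masses["leaf_deposit"] += f_int * dose
    masses["soil"] += (1.0 - f_int) * dose
    return replace(state, masses=masses)


@dataclass(frozen=True)
class SimulationResult:
    """Trajectory of a compartment simulation.

    ``times`` are days relative to the last application (negative before
    it); ``compartment_masses`` has one row per time and one column per
    entry of :data:`COMPARTMENTS`; ``edible_residue`` is mg/kg fresh weight
    in the harvested tissue.
    """

    pesticide: str
    crop: CropParameters
    schedule: ApplicationSchedule
    times: np.ndarray
    compartment_masses: np.ndarray
    cumulative_degraded: np.ndarray
    edible_residue: np.ndarray
    rates: TransferRates = field(repr=False, default=None)  # type: ignore[assignment]

    def state_at(self, index: int) -> CompartmentState:
        return CompartmentState(
            masses={name: float(self.compartment_masses[index, i])
                    for i, name in enumerate(COMPARTMENTS)},
            cumulative_degraded=float(self.cumulative_degraded[index]),
            time=float(self.times[index]))

    @property
    def trajectory(self) -> list[CompartmentState]:
        return [self.state_at(i) for i in range(len(self.times))]

    def compartment(self, name: str) -> np.ndarray:
        return self.compartment_masses[:, _IDX[name]]

    def total_applied(self) -> float:
        return sum(e.dose for e in self.schedule.events)

    def to_dataframe(self):
        """Tidy frame: time, one column per compartment, degraded, edible."""
        import pandas as pd
        data = {"time": self.times}
        for i, name in enumerate(COMPARTMENTS):
            data[name] = self.compartment_masses[:, i]
        data["cumulative_degraded"] = self.cumulative_degraded
        data["edible_residue"] = self.edible_residue
        return pd.DataFrame(data)


def _rk4_step(A: np.ndarray, y: np.ndarray, h: float) -> np.ndarray:
    """One classical RK4 step on the linear system y' = A y."""
    k1 = A @ y
    k2 = A @ (y + 0.5 * h * k1)
    k3 = A @ (y + 0.5 * h * k2)
    k4 = A @ (y + h * k3)
    return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def simulate_trajectories(pesticide: PesticideProperties, crop: CropParameters,
                          schedule: ApplicationSchedule, horizon: float,
                          step: float | None = None,
                          config: SimulatorConfig | None = None,
                          rates: TransferRates | None = None) -> SimulationResult:
    """Integrate the compartment system over a spray schedule.

    Parameters
    ----------
    horizon : float
        End of the simulation in days after the last application; must
        exceed the last event time (0).
    step : float, optional
        Fixed integration/output step in days (default from ``config``).
        Event times must fall on the step grid.
    config : SimulatorConfig, optional
        Process rates and numerics; ``rates`` overrides the resolved
        per-compound rate set entirely (used e.g. for oracle comparisons).

    Notes
    -----
    Day-0 convention: the state recorded at each event time **includes** that
    event's deposit, so day 0 carries the final spray and all earlier,
    partially decayed contributions.
    """
    config = config or SimulatorConfig()
    if step is None:
        step = config.step
    if step <= 0:
        raise ValidationError(f"step must be > 0, got {step}")
    if horizon <= schedule.last_time:
        raise ConfigurationError(
            f"horizon ({horizon}) must exceed the last application time "
            f"({schedule.last_time})")
    if rates is None:
        rates = TransferRates.from_properties(pesticide, config)
    A = rates.matrix()

    fastest = float(np.max(-np.diag(A)[:_N], initial=0.0))
    if fastest > 0 and step > 1.0 / (10.0 * fastest):
        msg = (f"integration step {step} d exceeds a tenth of the fastest "
               f"characteristic time ({1.0 / fastest:.3g} d)")
        if config.strict:
            raise StabilityError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    t0 = schedule.first_time
    n_steps = int(round((horizon - t0) / step))
    if not math.isclose(t0 + n_steps * step, horizon, rel_tol=0, abs_tol=1e-9):
        raise ValidationError(
            f"horizon − first event ({horizon - t0}) must be a multiple of "
            f"step ({step})")
    times = t0 + step * np.arange(n_steps + 1)

    event_steps: dict[int, float] = {}
    for e in schedule.events:
        idx = (e.time - t0) / step
        if abs(idx - round(idx)) > 1e-6:
            raise ValidationError(
                f"event time {e.time} does not fall on the step grid "
                f"(step={step})")
        event_steps[int(round(idx))] = event_steps.get(int(round(idx)), 0.0) + e.dose

    f_int = interception_fraction(crop.lai_at_application, config.kappa)
    out = np.zeros((n_steps + 1, _N + 1))
    y = np.zeros(_N + 1)
    propagator = expm(A * step) if config.method == "expm" else None

    if config.method not in ("expm", "rk4"):
        raise ConfigurationError(f"unknown method {config.method!r}")
    for i in range(n_steps + 1):
        dose = event_steps.get(i)
        if dose is not None:
            # recorded states at event times are post-application (day-0
            # residue is the maximum of the final-spray window)
            y = y.copy()
            y[_IDX["leaf_deposit"]] += f_int * dose
            y[_IDX["soil"]] += (1.0 - f_int) * dose
        out[i] = y
        if i == n_steps:
            break
        y = propagator @ y if propagator is not None else _rk4_step(A, y, step)

    masses = out[:, :_N]
    degraded = out[:, _N]
    edible = masses[:, _EDIBLE].sum(axis=1) / crop.yield_fresh * 1e6
    return SimulationResult(
        pesticide=pesticide.name, crop=crop, schedule=schedule, times=times,
        compartment_masses=masses, cumulative_degraded=degraded,
        edible_residue=edible, rates=rates)


def superpose_applications(curves: list[tuple[np.ndarray, np.ndarray]]
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise sum of per-application residue curves on a shared grid.

    Each curve is a ``(times, concentrations)`` pair; an application later
    than a given time contributes zero there (its curve must encode that).
    C_final(t) = Σ C_n(t) — valid because the fate system is linear.
    """
    if len(curves) < 1:
        raise ValidationError("need at least one curve")
    t0 = np.asarray(curves[0][0], dtype=float)
    total = np.zeros_like(np.asarray(curves[0][1], dtype=float))
    for times, conc in curves:
        times = np.asarray(times, dtype=float)
        conc = np.asarray(conc, dtype=float)
        if times.shape != t0.shape or not np.allclose(times, t0, atol=1e-9):
            raise AlignmentError("curves do not share a common time grid")
        if conc.shape != t0.shape:
            raise AlignmentError("curve values do not match its grid length")
        total = total + conc
    return t0, total


def residue_at_day(result: SimulationResult, day: float) -> float:
    """Edible residue (mg/kg) at a day after the last application, by linear
    interpolation on the output grid."""
    if day < result.times[0] or day > result.times[-1]:
        raise ValidationError(
            f"day {day} outside simulated range "
            f"[{result.times[0]}, {result.times[-1]}]")
    return float(np.interp(day, result.times, result.edible_residue))
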