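"""Tabular input/output for the pipeline.

All tables are plain CSV with fixed, documented units (days, mg/kg, kg/m²,
mg/kg bw/day). Column order is irrelevant; every load is deterministic and
round-trips losslessly through the matching ``write_*`` function.

File dialects
-------------
``pesticides.csv``
    one row per compound: ``name, molecular_weight, kow, mrl, mrl_commodity,
    t_half_plant, t_half_soil, m_applied, role`` plus one ``adi_<Agency>``
    column per agency (blank cell = no value for that agency).
``crop.csv``
    key–value sheet with columns ``parameter, value``; every field of
    :class:`~cropresid.datamodel.CropParameters` must be present (no
    defaults).
``applications.csv``
    ``pesticide, time, dose, dilution_volume`` (times relative to the last
    application).
``residues.csv``
    long format: ``pesticide, time, concentration, replicate``; replicates
    are preserved, not averaged.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
import yaml

from .datamodel import (ApplicationEvent, ApplicationSchedule, CropParameters,
                        PesticideProperties, ResidueSample, ResidueSeries)
from .errors import SchemaError, ValidationError

__all__ = [
    "load_pesticide_table", "write_pesticide_table",
    "load_crop_parameters", "write_crop_parameters",
    "load_application_schedules", "write_application_schedules",
    "load_residue_measurements", "write_residue_measurements",
    "load_config", "write_run_summary",
]

_PESTICIDE_COLUMNS = ["name", "molecular_weight", "kow", "mrl", "mrl_commodity",
                      "t_half_plant", "t_half_soil", "m_applied", "role"]
_ADI_PREFIX = "adi_"

_RESIDUE_COLUMNS = ["pesticide", "time", "concentration", "replicate"]


def _check_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def load_pesticide_table(path: str | Path) -> list[PesticideProperties]:
    """Read a pesticide property table (one compound per row).

    ADI columns are recognised by the ``adi_`` prefix; the remainder of the
    column name is kept verbatim as the agency label, so unknown agencies
    survive a round trip.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _PESTICIDE_COLUMNS, str(path))
    adi_cols = [c for c in df.columns if c.startswith(_ADI_PREFIX)]
    records: list[PesticideProperties] = []
    for idx, row in df.iterrows():
        adi = {c[len(_ADI_PREFIX):]: float(row[c])
               for c in adi_cols if pd.notna(row[c])}
        try:
            records.append(PesticideProperties(
                name=str(row["name"]),
                molecular_weight=float(row["molecular_weight"]),
                kow=float(row["kow"]),
                mrl=float(row["mrl"]),
                mrl_commodity=str(row["mrl_commodity"]),
                t_half_plant=float(row["t_half_plant"]),
                t_half_soil=float(row["t_half_soil"]),
                m_applied=float(row["m_applied"]),
                adi_by_agency=adi,
                role_label=str(row["role"]),
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {idx}: {exc}") from exc
    return records


def write_pesticide_table(pesticides: Iterable[PesticideProperties],
                          path: str | Path) -> None:
    pesticides = list(pesticides)
    agencies = sorted({a for p in pesticides for a in p.adi_by_agency})
    rows = []
    for p in pesticides:
        row: dict[str, Any] = {
            "name": p.name, "molecular_weight": p.molecular_weight,
            "kow": p.kow, "mrl": p.mrl, "mrl_commodity": p.mrl_commodity,
            "t_half_plant": p.t_half_plant, "t_half_soil": p.t_half_soil,
            "m_applied": p.m_applied, "role": p.role_label,
        }
        for a in agencies:
            row[_ADI_PREFIX + a] = p.adi_by_agency.get(a)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def load_crop_parameters(path: str | Path) -> CropParameters:
    """Read a key–value crop sheet; every field must be explicit."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ["parameter", "value"], str(path))
    mapping = dict(zip(df["parameter"].astype(str), df["value"]))
    field_names = [f.name for f in dataclasses.fields(CropParameters)]
    missing = [f for f in field_names if f not in mapping]
    if missing:
        raise SchemaError(f"{path}: missing crop parameter(s) {missing}")
    return CropParameters(**{f: float(mapping[f]) for f in field_names})


def write_crop_parameters(crop: CropParameters, path: str | Path) -> None:
    rows = [{"parameter": f.name, "value": getattr(crop, f.name)}
            for f in dataclasses.fields(CropParameters)]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def load_application_schedules(path: str | Path) -> dict[str, ApplicationSchedule]:
    """Read spray schedules, one row per event, grouped by pesticide."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ["pesticide", "time", "dose"], str(path))
    schedules: dict[str, ApplicationSchedule] = {}
    for name, grp in df.groupby("pesticide", sort=False):
        grp = grp.sort_values("time")
        events = tuple(
            ApplicationEvent(
                time=float(r["time"]), dose=float(r["dose"]),
                dilution_volume=(float(r["dilution_volume"])
                                 if "dilution_volume" in grp.columns
                                 and pd.notna(r.get("dilution_volume"))
                                 else None))
            for _, r in grp.iterrows()
        )
        schedules[str(name)] = ApplicationSchedule(events=events)
    return schedules


def write_application_schedules(schedules: dict[str, ApplicationSchedule],
                                path: str | Path) -> None:
    rows = [{"pesticide": name, "time": e.time, "dose": e.dose,
             "dilution_volume": e.dilution_volume}
            for name, sched in schedules.items() for e in sched.events]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def load_residue_measurements(path: str | Path) -> list[ResidueSeries]:
    """Read long-format residue measurements grouped into per-pesticide series.

    Within each series samples are sorted by time; replicates are preserved.
    Duplicate (pesticide, time, replicate) keys are an error — they would
    silently double-weight observations downstream.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _RESIDUE_COLUMNS, str(path))
    if df[["time", "concentration"]].isna().any().any():
        raise ValidationError(f"{path}: missing time/concentration values")
    dup = df.duplicated(subset=["pesticide", "time", "replicate"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["pesticide", "time", "replicate"]]
        raise ValidationError(
            f"{path}: duplicate (pesticide, time, replicate) rows:\n"
            f"{keys.to_string(index=False)}")
    series: list[ResidueSeries] = []
    for name, grp in df.groupby("pesticide", sort=False):
        samples = tuple(
            ResidueSample(time=float(r["time"]),
                          concentration=float(r["concentration"]),
                          replicate_id=str(r["replicate"]))
            for _, r in grp.sort_values(["time", "replicate"]).iterrows()
        )
        series.append(ResidueSeries(pesticide=str(name), samples=samples))
    return series


def write_residue_measurements(series: Iterable[ResidueSeries],
                               path: str | Path) -> None:
    rows = [{"pesticide": s.pesticide, "time": smp.time,
             "concentration": smp.concentration, "replicate": smp.replicate_id}
            for s in series for smp in s.samples]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML run configuration (paths, seed, simulator options)."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return config


def write_run_summary(summary: dict[str, Any], path: str | Path) -> None:
    """Write a JSON run summary (parameters echoed for reproducibility)."""
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True,
                                     default=str) + "\n")
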