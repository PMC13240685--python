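"""Bundled example scenario: a greenhouse spinach residue trial.

These tables describe a published-style worst-case greenhouse scenario for
Korean spinach production: nine commonly used compounds (three fungicides
sprayed three times, six insecticides sprayed twice, 7-day intervals), the
spinach crop parameterisation used by the simulator, and a 15-compound
scenario risk table of model-calculated residues on the {0, 3, 7, 14}-day
grid with each compound's most conservative agency ADI.

They serve as a realistic, fixed input set for the worked examples, the
tests and the acceptance script; units follow the package conventions
(days, mg/kg, kg/m², mg/kg bw/day).
"""

from __future__ import annotations

import pandas as pd

from .datamodel import ApplicationSchedule, CropParameters, PesticideProperties

__all__ = [
    "spinach_crop_parameters", "lettuce_crop_parameters",
    "pesticide_properties", "default_schedules", "risk_scenario",
    "RISK_DAY_GRID",
]

RISK_DAY_GRID = (0.0, 3.0, 7.0, 14.0)

DEFAULT_SPRAY_INTERVAL_DAYS = 7.0
N_APPLICATIONS = {"fungicide": 3, "insecticide": 2}


def spinach_crop_parameters() -> CropParameters:
    """Spinach parameter set (soil, yield, partitioning, LAI).

    The harvested leaf cover is reported with area units in the source
    sheet but is treated as the dimensionless 2.6 here, matching the LAI
    rows.
    """
    return CropParameters(
        soil_organic_carbon=0.02, soil_ph=4.7, soil_depth=0.5,
        yield_fresh=2.65, root_fraction=0.09, stem_fraction=0.15,
        leaf_fraction=0.85, lai_start=0.03, lai_harvest=2.6,
        lai_at_application=2.6, leaf_cover_harvest=2.6)


def lettuce_crop_parameters() -> CropParameters:
    """Default model-plant (lettuce) parameter set.

    Lettuce sheets leave LAI at application/harvest unspecified; those three
    fields are synthetic fills copied from the spinach canopy (2.6) so the
    record validates — use only where the canopy terms are irrelevant.
    """
    return CropParameters(
        soil_organic_carbon=0.02, soil_ph=7.0, soil_depth=0.3,
        yield_fresh=3.33, root_fraction=0.09, stem_fraction=0.12,
        leaf_fraction=0.88, lai_start=0.03, lai_harvest=2.6,
        lai_at_application=2.6, leaf_cover_harvest=2.6)


# name: (MW g/mol, Kow, MRL mg/kg, commodity, t1/2 plant d, t1/2 soil d,
#        m_applied kg/m², role, {agency: ADI})
_PESTICIDES = {
    "pencycuron": (328.84, 4.9e3, 20.0, "leafy vegetable", 4.3, 64.0, 2.0e-4,
                   "fungicide", {"Japan": 0.053}),
    "propamocarb": (188.30, 6.0e3, 25.0, "leafy vegetable", 5.7, 35.4, 1.3e-4,
                    "fungicide", {"Europe": 0.29}),
    "cypermethrin": (416.30, 8.6e4, 5.0, "spinach", 4.5, 31.0, 1.0e-4,
                     "insecticide", {"Korea": 0.02}),
    "deltamethrin": (505.20, 1.0e7, 0.05, "spinach", 3.8, 24.0, 2.0e-6,
                     "insecticide", {"CODEX": 0.01}),
    "thiamethoxam": (291.71, 7.0e1, 5.0, "leafy vegetable", 3.9, 39.0, 1.0e-5,
                     "insecticide", {"USA": 0.012}),
    "fenazaquin": (306.40, 2.6e4, 0.7, "leafy vegetable", 3.8, 30.5, 6.7e-6,
                   "insecticide", {"Europe": 0.005}),
    "dinotefuran": (202.21, 2.6e1, 10.0, "spinach", 3.0, 82.0, 1.0e-5,
                    "insecticide", {"USA": 0.02}),
    "cymoxanil": (198.18, 4.4e1, 19.0, "spinach", 1.4, 25.3, 2.1e-5,
                  "fungicide", {"Korea": 0.013}),
    "fenpropathrin": (349.42, 5.0e3, 5.0, "spinach", 2.0, 28.0, 1.0e-5,
                      "insecticide", {"CODEX": 0.03}),
}


def pesticide_properties() -> list[PesticideProperties]:
    """The nine trial compounds with their constants and lowest-agency ADI."""
    return [
        PesticideProperties(
            name=name, molecular_weight=mw, kow=kow, mrl=mrl,
            mrl_commodity=commodity, t_half_plant=thp, t_half_soil=ths,
            m_applied=m, role_label=role, adi_by_agency=dict(adi))
        for name, (mw, kow, mrl, commodity, thp, ths, m, role, adi)
        in _PESTICIDES.items()
    ]


def default_schedules(
        pesticides: list[PesticideProperties] | None = None,
        interval_days: float = DEFAULT_SPRAY_INTERVAL_DAYS,
) -> dict[str, ApplicationSchedule]:
    """Trial spray schedules: fungicides 3×, insecticides 2×, fixed interval,
    last spray at day 0, dose = the compound's per-application mass."""
    pesticides = pesticides if pesticides is not None else pesticide_properties()
    return {
        p.name: ApplicationSchedule.from_interval(
            n_applications=N_APPLICATIONS[p.role_label],
            dose=p.m_applied, interval_days=interval_days,
            dilution_volume=200.0)
        for p in pesticides
    }


# name: (ADI mg/kg bw/day, agency,
#        {day: (model-calculated mg/kg, published HQ %)})
_RISK_SCENARIO = {
    "pencycuron": (0.053, "Japan",
                   {14: (2.56, 2.13), 7: (4.95, 4.11),
                    3: (9.39, 7.79), 0: (16.41, 13.62)}),
    "propamocarb": (0.29, "Europe",
                    {14: (8.63, 7.17), 7: (21.10, 17.52),
                     3: (34.32, 28.49), 0: (39.74, 32.99)}),
    "cypermethrin": (0.02, "Korea",
                     {14: (0.33, 0.72), 7: (1.54, 3.39),
                      3: (3.91, 8.61), 0: (7.39, 16.26)}),
    "deltamethrin": (0.01, "CODEX",
                     {14: (0.03, 0.12), 7: (0.20, 0.90),
                      3: (0.64, 2.81), 0: (1.22, 5.38)}),
    "thiamethoxam": (0.012, "USA",
                     {14: (1.31, 4.79), 7: (2.36, 8.67),
                      3: (4.32, 15.85), 0: (7.70, 28.25)}),
    "fenazaquin": (0.005, "Europe",
                   {14: (0.06, 0.56), 7: (0.30, 2.60),
                    3: (0.87, 7.61), 0: (1.89, 16.61)}),
    "dinotefuran": (0.02, "USA",
                    {14: (0.40, 0.87), 7: (2.17, 4.78),
                     3: (11.25, 24.75), 0: (12.08, 26.57)}),
    "cymoxanil": (0.013, "Korea",
                  {14: (0.87, 2.93), 7: (1.29, 4.36),
                   3: (2.27, 7.70), 0: (7.19, 24.34)}),
    "fenpropathrin": (0.03, "CODEX",
                      {14: (0.06, 0.09), 7: (0.17, 0.25),
                       3: (0.92, 1.35), 0: (3.80, 5.57)}),
    "mandipropamid": (0.03, "Europe",
                      {14: (0.58, 0.85), 7: (1.82, 2.66),
                       3: (4.81, 7.06), 0: (10.77, 15.80)}),
    "azoxystrobin": (0.18, "Japan",
                     {14: (2.18, 2.13), 7: (4.00, 3.91),
                      3: (8.09, 7.91), 0: (16.00, 15.65)}),
    "fluopicolid": (0.045, "Japan",
                    {14: (2.44, 2.39), 7: (3.46, 3.38),
                     3: (4.49, 4.39), 0: (5.12, 5.01)}),
    "cyantraniliprole": (0.057, "Korea",
                         {14: (0.92, 0.71), 7: (1.38, 1.06),
                          3: (1.80, 1.39), 0: (2.06, 1.59)}),
    "abamectin": (0.002, "Korea",
                  {14: (0.01, 0.01), 7: (0.02, 0.02),
                   3: (0.05, 0.04), 0: (0.09, 0.07)}),
    "pymetrozine": (0.0038, "USA",
                    {14: (0.03, 0.33), 7: (0.24, 2.81),
                     3: (1.00, 11.52), 0: (2.61, 30.28)}),
}


def risk_scenario() -> pd.DataFrame:
    """Scenario risk table for 15 spinach pesticides.

    One row per pesticide × day after the last application, with the
    model-calculated edible residue, the compound's lowest agency ADI and
    the HQ as published in the scenario sheet (``hq_printed``). Three
    blocks (propamocarb, azoxystrobin, abamectin) are known to carry
    ADI/HQ inconsistencies — :func:`cropresid.risk.audit_risk_table`
    localises them.
    """
    rows = []
    for name, (adi, agency, by_day) in _RISK_SCENARIO.items():
        for day in sorted(by_day):
            conc, hq = by_day[day]
            rows.append({"pesticide": name, "adi": adi, "adi_agency": agency,
                         "day": float(day), "concentration": conc,
                         "hq_printed": hq})
    return pd.DataFrame(rows)
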