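"""Simulate compartment trajectories for a three-spray fungicide schedule.

Runs the linear fate model for pencycuron on spinach (three applications,
7 days apart) and prints where the mass sits at harvest-relevant days.
"""

from cropresid import residue_at_day, simulate_trajectories
from cropresid.datasets import (default_schedules, pesticide_properties,
                                spinach_crop_parameters)

crop = spinach_crop_parameters()
pency = next(p for p in pesticide_properties() if p.name == "pencycuron")
schedule = default_schedules([pency])["pencycuron"]

result = simulate_trajectories(pency, crop, schedule, horizon=21.0)

print(f"{pency.name}: {schedule.n_applications} applications of "
      f"{pency.m_applied:.1e} kg/m², last at day 0")
for day in (0, 3, 7, 14):
    print(f"  day {day:>2}: edible residue "
          f"{residue_at_day(result, day):7.2f} mg/kg")

final = result.state_at(len(result.times) - 1)
print("day 21 mass split (kg/m²):")
for comp, mass in final.masses.items():
    print(f"  {comp:<12} {mass:.3e}")
print(f"  {'degraded':<12} {final.cumulative_degraded:.3e}")
print("Surface deposit and air empty fastest; soil persists on its longer")
print("half-life; the edible residue is the aerial (deposit+leaf+stem) mass")
print("per kg of fresh yield.")
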