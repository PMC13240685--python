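# Methods

`cropresid` implements the quantitative core of a pesticide residue trial on
a leafy vegetable: dissipation kinetics, a compartmental fate simulator,
model-validation statistics, and a dietary risk assessment. This note
records the models, their assumptions, the defaults and why they were
chosen, and what the package's synthetic data can and cannot demonstrate.

## Dissipation kinetics

Residue decay in edible tissue is modelled as single first-order kinetics,

    C(t) = C0 · e^(−k t),        t_1/2 = ln 2 / k,

with C in mg/kg fresh weight and t in days after the last application. Two
estimators are exposed:

- **nonlinear** (default): least squares on the original scale via
  Levenberg–Marquardt, initialised with C0 from the earliest observation
  and k from a log-linear regression on the positive concentrations. The
  initialisation is deterministic, so fits are reproducible. Convergence
  tolerance is 1e-10 on parameters and objective, capped at 10,000
  function evaluations; failure raises instead of returning a partial fit.
- **loglinear**: ordinary least squares of ln C on t. Zero concentrations
  are excluded here (the log is undefined) but are retained by the
  nonlinear objective, which is one reason the nonlinear route is the
  default for real data with values near the quantitation limit.

R² is always reported on the original scale so the two methods are
comparable. Replicates are pooled into the objective with equal weight by
default; per-timepoint averaging is available but changes the implicit
weighting and is off unless asked for. A series whose optimal rate constant
is non-positive raises a `NonDissipatingError` — clamping k at zero would
silently convert a non-decaying series into an infinite half-life.

No biphasic or double-exponential decay is offered: short pre-harvest
windows on leafy crops rarely resolve a second phase, and the downstream
risk arithmetic assumes a single rate.

## Compartment simulator

The simulator is a deliberately small, fully specified **linear
first-order transfer system** over six compartments — leaf-surface deposit,
leaf tissue, stem, root, soil, air — plus a cumulative-degraded pool.
Published multimedia crop models resolve many more processes; this system
keeps the behaviour that matters for edible-residue prediction (canopy
interception, surface-to-tissue transfer, Kow-dependent translocation,
half-life-calibrated decay, multi-application superposition) while staying
analytically checkable.

Processes and defaults (all rates in day⁻¹):

| process | parameter | default | rationale |
|---|---|---|---|
| canopy interception at spray | κ (Beer–Lambert) | 0.4 | mid-range extinction coefficient for leafy canopies; at LAI 2.6 it intercepts 65% of the dose |
| deposit → leaf penetration | `k_penetration` | 0.1 | cuticular uptake over a few days |
| deposit → air wash-off/volatilisation | `k_washoff` | 0.1 | drives the rapid surface-deposit decline |
| leaf ↔ stem, stem ↔ root translocation | 0.05 / 0.02 / 0.02 | × logistic(log₁₀Kow; mid 3.0, width 0.8) | systemic (low-Kow) compounds translocate; lipophilic ones stay put |
| root → stem return, soil → root uptake | 0 | off | negligible over a ≤3-week pre-harvest window; keeps soil decay exactly on its measured half-life |
| air loss | `k_air_loss` | 2.0 | the air pool is a short-lived sink |

**Calibration.** Each compartment degrades in place; plant-side degradation
starts from k_plant = ln2/t_half_plant and soil from ln2/t_half_soil, the
half-lives measured in the matching dissipation trial. Because wash-off
removes mass from the edible aggregate without being "degradation", the
deposit's in-place degradation is debited by the wash-off rate (floored at
zero), and likewise the stem's by its root export. With the root-return
flow off, the edible aggregate (deposit + leaf + stem) then decays at
exactly k_plant — the simulator and the fitted kinetics agree by
construction, and transfers redistribute mass *within* the edible pool
rather than distorting its decay. Disabling the compensation interprets
every rate literally.

**Numerics.** Between spray events the system is a constant-coefficient
linear ODE. The default integrator is fixed-step classical RK4 at 0.01 day;
an exact matrix-exponential propagator (`method="expm"`) is available and
doubles as the test oracle. The generator matrix's columns sum to zero
exactly, so any consistent one-step method conserves total mass to
round-off; mass balance is asserted at 1e-9 relative in the tests and holds
at ~1e-15 in practice. A step coarser than a tenth of the fastest
characteristic time triggers a warning (an error in strict mode).

**Conventions.** Time 0 is the last application; earlier sprays carry
negative times. The state recorded at an event time is post-application, so
day-0 residue is the maximum of the final-spray window. Edible residue is
(deposit + leaf + stem) mass ÷ fresh yield × 10⁶ (mg/kg). The spray-solution
volume (200 L per 10 a) is metadata only; the dose is the active-ingredient
mass per m². Growth dilution is not modelled: the bundled crop sheet fixes
LAI at application and at harvest to the same 2.6, so canopy and biomass are
treated as constant over the simulated window. The crop sheet's "leaf cover
at harvest, 2.6 m²" is treated as the dimensionless 2.6, consistent with
the LAI rows it accompanies.

Because the system is linear, an n-application run equals the pointwise sum
of n single-application runs (superposition), and doubling every dose
doubles every trajectory — both are asserted to 1e-9 relative in the tests.
Near-zero stem/root trajectories are reported as computed, never suppressed.

## Validation statistics

For measured Aᵢ vs predicted Fᵢ: R² = 1 − SSE/SST (unclamped; a constant
measured series raises rather than dividing by zero), MAE, RRMSE and RMSLE
(natural log on 1 + x). RRMSE is RMSE divided by the quadratic mean of the
predictions, ×100 — scale-invariant and independent of n; a variant
dividing by the total ΣFᵢ² inside the radical is kept behind
`normalization="total"` because both readings of the conventional formula
circulate. A prediction is flagged *reliable* when MAE < MRL (strict
inequality): errors smaller than the regulatory ceiling cannot by
themselves flip a compliance decision.

## Risk assessment

EDI = C × (daily intake / 1000) / body weight, in mg/kg bw/day. The
published convention sometimes writes EDI without the body-weight division,
but the unit it is reported in (mg/kg bw/day) requires it, so the division
is always applied. The default consumption profile is 26.4 g spinach/day
for a 60 kg consumer — a per-capita figure consistent with Korean dietary
surveys, and the factor (4.4×10⁻⁴ kg/kg bw/day) that reproduces the
bundled scenario's published EDI column; both numbers are overridable.

HQ = EDI/ADI × 100, against the **lowest** ADI across agencies (Korea,
CODEX, Japan, USA, Europe; ties broken lexicographically for determinism).
HQ < 100% is the conventional negligible-risk bound; the pre-harvest
interval uses a stricter default screen of 10% and returns the earliest
*evaluated* day below it (no interpolation between grid days; default grid
{0, 3, 7, 14}).

`audit_risk_table` recomputes HQ from each row's concentration and ADI and
flags disagreements with the published HQ. In the bundled scenario three
blocks (propamocarb, azoxystrobin, abamectin) fail the audit: their
published HQs imply ADIs of ≈0.053, ≈0.045 and ≈0.057 mg/kg bw/day rather
than the printed 0.29, 0.18 and 0.002 — a row-shift-like inconsistency the
package flags but does not silently correct. Rows printed with only two
decimals (e.g. 0.03 mg/kg) cannot be audited at 0.5% relative purely
because of rounding; block-level judgements therefore use the day-0 rows,
which carry 3+ significant digits.

## Synthetic data

The generator emulates what the analysis assumes: first-order decay with
**multiplicative lognormal noise of unit median** and fixed CV (residue
determinations are positive with roughly constant relative spread, and unit
median keeps the log-linear fit unbiased for the underlying curve); a
default sampling grid of {0, 1, 3, 5, 7, 10, 14} days × 3 replicates;
compound parameters drawn on realistic scales (plant half-life 1–7 d, soil
half-life 20–90 d, log₁₀Kow 1–7, dose 2×10⁻⁶–2×10⁻⁴ kg/m², log-uniform
where the range spans orders of magnitude); fungicide-like compounds
sprayed three times and insecticide-like twice at 7-day intervals. The
true day-0 concentration is derived from dose × interception ÷ yield,
which spans ≈0.5–49 mg/kg — the range leafy-crop trials report. One global
seed drives a named substream per output table, so adding a table never
perturbs existing draws.

What the synthetic data does **not** contain: quantitation-limit censoring,
recovery-correction error, temperature- or humidity-dependent rates, plot-
to-plot heterogeneity, or any departure from first-order decay. Passing
recovery tests therefore demonstrate the estimators and the pipeline
plumbing under the model's own assumptions, not robustness to field
artefacts.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` run the full pipeline at trial
scale: 9–25 synthetic compounds, 100-seed recovery batches, 1,000 random
pairs for metric-oracle equivalence, and 21-day simulations at a 0.01-day
step — sizes chosen to match the designs the methods target while keeping a
full run in seconds. All randomness flows from explicit integer seeds;
every reported number is recomputed from scratch at run time.

## Known limitations

- The compartment system is a first-order surrogate, not a mechanistic
  multimedia model: no photolysis spectra, no metabolite tracking, no
  regional fate (leaching, runoff, advection), no temperature dependence.
- Constant-canopy assumption: growth dilution between application and
  harvest is ignored (appropriate when LAI is already at harvest value at
  application, as in the bundled crop sheet).
- Risk assessment is per-compound chronic screening only: no cumulative
  exposure across compounds, no probabilistic intake distributions, no
  sub-population stratification.
- The pre-harvest interval is resolved only to the evaluated day grid.
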