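"""Generate a full synthetic residue trial and run the whole pipeline.

Nine compounds (3 fungicide-like × 3 sprays, 6 insecticide-like × 2
sprays) are drawn on realistic parameter scales; residue series are fitted
and the recovered kinetics compared to the generator's ground truth.
"""

from cropresid import fit_first_order, generate_study

study = generate_study(n_pesticides=9, seed=7, noise_cv=0.1)

print(f"{'compound':<13}{'role':<13}{'true t1/2':>10}{'fitted':>8}"
      f"{'rel err %':>10}{'R²':>7}")
for series in study.residue_series:
    truth = study.ground_truth[series.pesticide]
    fit = fit_first_order(series)
    rel = 100 * abs(fit.t_half - truth["t_half"]) / truth["t_half"]
    role = next(p.role_label for p in study.pesticides
                if p.name == series.pesticide)
    print(f"{series.pesticide:<13}{role:<13}{truth['t_half']:>10.2f}"
          f"{fit.t_half:>8.2f}{rel:>10.1f}{fit.r2_fit:>7.3f}")
print("Half-lives are recovered to a few percent from 7 timepoints × 3")
print("replicates at 10% noise — the precision a residue trial of this")
print("design can support.")
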