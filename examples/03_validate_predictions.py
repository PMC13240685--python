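"""Score model predictions against measurements with R², MAE, RRMSE, RMSLE.

Builds a noisy 'measured' series, predicts it with a fitted decay curve,
and bundles the four validation statistics plus the MRL reliability screen
(MAE must stay below the commodity's maximum residue limit).
"""

import numpy as np

from cropresid import (GeneratorSpec, PairedSeries, evaluate_pair,
                       fit_first_order, generate_residue_series,
                       predict_residue)

series = generate_residue_series(GeneratorSpec(
    true_c0=16.4, true_k=0.16, noise_cv=0.1, n_replicates=3, seed=11,
    pesticide="pencycuron-like"))
fit = fit_first_order(series)

measured = np.array(series.concentrations())
predicted = predict_residue(fit, series.times())
report = evaluate_pair(PairedSeries(a=measured, f=predicted,
                                    pesticide=series.pesticide), mrl=20.0)

print(f"n={report.n} paired points")
print(f"R²    = {report.r2:.4f}   (fraction of measured variance explained)")
print(f"MAE   = {report.mae:.3f} mg/kg")
print(f"RRMSE = {report.rrmse:.2f} %   (RMSE relative to prediction scale)")
print(f"RMSLE = {report.rmsle:.4f}   (log-scale error, outlier-robust)")
print(f"MAE < MRL(20 mg/kg)? {report.mrl_reliable} -> prediction errors are "
      "within regulatory tolerance")
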