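"""Pseudo individual-patient data from a digitized survival curve.

Simulates a 500-subject trial arm from a known log-logistic truth,
"digitizes" its Kaplan-Meier curve (as one would trace a published
figure), reconstructs patient-level records from the coordinates and the
numbers-at-risk row, and refits the parametric model — the preprocessing
path that turns published survival figures into model inputs.
"""

import numpy as np

from nsclc_cea import (
    LogLogisticParams,
    SimulationTruth,
    digitize,
    fit_exponential_mle,
    fit_loglogistic_mle,
    fit_weibull_mle,
    reconstruct_pseudo_ipd,
    select_model_aic,
    simulate_ipd,
)

truth = LogLogisticParams(scale=0.07476837, shape=1.52037)  # median ~13.4 months
ipd = simulate_ipd(SimulationTruth(truth, n=500, censoring_rate=0.2, seed=1))
print(f"simulated {len(ipd)} subjects, {ipd.n_events} events")

grid = np.linspace(0.0, float(np.quantile(ipd.times, 0.98)), 200)
curve, risk = digitize(ipd, grid, risk_grid=grid[::20])
print(f"digitized {curve.times.size} curve points, {risk.times.size} at-risk rows")

rec = reconstruct_pseudo_ipd(curve, risk)
print(f"reconstructed {len(rec)} records, {rec.n_events} events")

fits = []
for name, fitter, k in [
    ("loglogistic", fit_loglogistic_mle, 2),
    ("weibull", fit_weibull_mle, 2),
    ("exponential", fit_exponential_mle, 1),
]:
    params, ll = fitter(rec.times, rec.events)
    fits.append((name, k, ll))
    if name == "loglogistic":
        est = params

print("\nAIC ranking (lower is better):")
for name, k, ll, aic in select_model_aic(fits):
    print(f"  {name:12s} k={k}  logL={ll:9.2f}  AIC={aic:9.2f}")

print(
    f"\nrefit scale {est.scale:.4f} (truth {truth.scale:.4f}), "
    f"shape {est.shape:.3f} (truth {truth.shape:.3f}) — the digitize/"
    "reconstruct round trip preserves the curve well enough to recover\n"
    "the generating parameters within a few percent."
)
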