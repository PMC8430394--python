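"""Probabilistic sensitivity analysis and acceptability curve.

Draws every distributional parameter 1,000 times (beta for probabilities
and utilities, lognormal for costs, normal for weight, log-scale normal
for hazard ratios), re-runs both arms per draw, and reports the
probability that the combination is cost-effective across
willingness-to-pay thresholds.
"""

from nsclc_cea import make_fixture_config, run_psa

config = make_fixture_config()
psa = run_psa(config, n_iterations=1000, seed=227)

d = psa.samples
print(f"draws: {len(d)}")
print(f"mean incremental cost : ${d.delta_cost.mean():,.0f}")
print(f"mean incremental QALY : {d.delta_qaly.mean():.3f}")
print()
print("cost-effectiveness acceptability (combination vs chemotherapy):")
for wtp in (50_000, 100_000, 150_000, 200_000):
    print(f"  WTP ${wtp:>7,}/QALY : {100 * psa.acceptability_at(wtp):5.1f}%")
print()
print(
    "Around the base-case ICER the curve crosses 50%: at $100,000/QALY\n"
    "the decision is a coin flip, at $150,000/QALY the combination is\n"
    "favoured in about two thirds of parameter draws."
)
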