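"""Base-case cost-effectiveness of nivolumab+ipilimumab vs chemotherapy.

Builds the packaged configuration (log-logistic chemotherapy survival
baselines, trial hazard ratios, unit prices, utilities, adverse-event
profile), runs both arms over a lifetime horizon of 6-week cycles, and
prints discounted costs/QALYs, undiscounted life-years, and the
incremental cost-effectiveness ratios.
"""

from nsclc_cea import make_fixture_config, run_base_case

config = make_fixture_config()
res = run_base_case(config)

print(res.summary().to_string(index=False, float_format=lambda x: f"{x:,.2f}"))
print()
icer = res.icer
print(f"incremental cost       : ${icer.delta_cost:,.0f}")
print(f"incremental life-years : {icer.delta_ly:.2f}")
print(f"incremental QALYs      : {icer.delta_qaly:.2f}")
print(f"ICER per life-year     : ${icer.icer_per_ly:,.0f}")
print(f"ICER per QALY          : ${icer.icer_per_qaly:,.0f}")
print()
print(
    "An ICER near $100,000/QALY means the combination buys one extra\n"
    "quality-adjusted life-year at roughly the lower bound of the usual\n"
    "US willingness-to-pay range ($100,000-$150,000 per QALY)."
)
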