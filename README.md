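# nsclc-cea

A cohort decision model for the cost-effectiveness of first-line
**nivolumab + ipilimumab versus platinum-doublet chemotherapy** in advanced
non-small-cell lung cancer (NSCLC), from the US payer perspective.

The package is aimed at health-economics and HTA analysts who want a
tested, scriptable implementation of a trial-based oncology
cost-utility model: survival extrapolation from digitized Kaplan–Meier
curves, a three-state partitioned-survival cohort engine, drug/administration/
adverse-event costing, and the standard uncertainty analyses (tornado,
probabilistic sensitivity analysis, subgroups).

## The model

Three health states — progression-free (PFS), progressed disease (PD),
dead — with occupancy read off parametric survival curves at 6-week cycle
boundaries:

```
PFS(t)   = S_pfs(t) · S_bg(t)
Death(t) = 1 − S_os(t) · S_bg(t)
PD(t)    = 1 − PFS(t) − Death(t)
```

The chemotherapy arm's OS and PFS follow log-logistic baselines
`S(t) = 1 / (1 + (λt)^γ)` (t in months; median `1/λ`), fitted to
pseudo individual-patient data reconstructed from digitized trial curves.
The combination arm applies the trial hazard ratios (OS 0.73, PFS 0.79)
to those baselines as proportional hazards, `S^HR`. Background (other-cause)
mortality `S_bg` comes from an annual life table, combined on the additive-
hazards scale. Costs cover weight/BSA-based drug acquisition (nivolumab
3 mg/kg q2w + ipilimumab 1 mg/kg q6w while progression-free, up to ~2 years;
pemetrexed/gemcitabine + cisplatin induction then pemetrexed maintenance),
Medicare-schedule infusion fees, incidence-weighted adverse-event management,
and second-line therapy while progressed. Outcomes are quality-adjusted with
state utilities (PFS 0.71, PD 0.67) and one-off adverse-event disutilities.
Costs and QALYs are discounted at 3%/year; life-years are reported
undiscounted. The headline result is the incremental cost-effectiveness
ratio, ICER = ΔCost / ΔQALY.

## Worked example

```python
from nsclc_cea import make_fixture_config, run_base_case

res = run_base_case(make_fixture_config())
print(res.summary())
```

Running `python examples/01_base_case.py` prints:

```
            strategy       cost  life_years  qalys
nivolumab+ipilimumab 217,208.95        3.04   1.82
        chemotherapy 158,009.36        2.03   1.24

incremental cost       : $59,200
incremental life-years : 1.01
incremental QALYs      : 0.58
ICER per life-year     : $58,822
ICER per QALY          : $101,999
```

The combination adds about one (undiscounted) life-year and 0.58
discounted QALYs per patient at an extra discounted cost of ~$59,000 —
an ICER of roughly $102,000 per QALY, inside the conventional US
willingness-to-pay range of $100,000–$150,000/QALY.

The other examples walk through each capability:

| script | what it shows |
| --- | --- |
| `examples/01_base_case.py` | deterministic two-arm run and ICERs |
| `examples/02_tornado.py` | one-way sensitivity: body weight and the OS hazard ratio dominate; either can push the ICER past $150k/QALY |
| `examples/03_psa_ceac.py` | 1,000-draw PSA; acceptability ≈51% at $100k and ≈67% at $150k per QALY |
| `examples/04_subgroups.py` | PD-L1 ≥1% / ≥50% / <1% subgroup ICERs (all below $150k/QALY) |
| `examples/05_curve_reconstruction.py` | digitized-curve → pseudo-IPD → parametric refit round trip with AIC ranking |

Every input lives in a `ModelConfig` (YAML-serialisable); structural
switches — hazard-ratio convention (proportional hazards vs accelerated
failure time), second-line costing mode, treatment-stop rule, histology
mix, trace mode — are explicit fields, so scenario analyses are one
`dataclasses.replace` away.

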