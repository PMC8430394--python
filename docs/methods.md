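# Methods

This note documents the model structure, the numerical choices, and the
reasoning behind the defaults, in the spirit of a model appendix.

## Survival model

The chemotherapy (reference) arm is described by log-logistic survival
functions under the scale/shape convention

    S(t) = 1 / (1 + (λ t)^γ),   t in months,

with OS (λ = 0.07476837, γ = 1.52037) and PFS (λ = 0.1937502,
γ = 1.950076) baselines. The time scale is months: under this
parameterisation the implied chemotherapy medians are 1/λ ≈ 13.4 months
(OS) and ≈ 5.2 months (PFS), consistent with first-line platinum-doublet
outcomes in advanced NSCLC, whereas a week or cycle scale would give
implausible medians. The parameterisation is pluggable — exponential and
Weibull families are provided and enter the AIC model-ranking path.

The combination arm is derived from the fitted baselines via the trial
hazard ratios (OS 0.73, PFS 0.79). The default application rule is
proportional hazards, `S_new = S_base^HR`, the standard practice when a
trial reports HRs against a parametric control extrapolation. An
accelerated-failure-time alternative, `S_new(t) = S_base(HR·t)`, is
available behind `hr_mode="aft"`. Hazard ratios are applied over the whole
horizon (no waning).

Maximum-likelihood fitting of censored records maximises
Σ[event·log f(t) + (1−event)·log S(t)] over log-scale parameters
(positivity by construction) with a deterministic three-point multistart
(Nelder–Mead, xatol 1e-8); there is no randomness in fitting. The
exponential rate has the closed form events/exposure. AIC = 2k − 2·logL,
ranked ascending with ties broken by parameter count then name.

## Curve reconstruction

Published figures give only the Kaplan–Meier curve; parametric fitting
needs patient-level records. `reconstruct_pseudo_ipd` walks each
numbers-at-risk interval, spreads a trial censoring count uniformly over
the interval, steps the product-limit relation through the digitized
drops (event count at each drop from the current at-risk count and the
reconstructed KM level, with running-sum rounding so interval totals are
conserved), and iterates the censoring count until the at-risk count at
the interval end matches the printed one. Event times sit at the
digitized drop times; censoring times at uniform positions inside the
interval. Without a risk table the degraded mode takes a stated total n,
treats every drop as events, and censors the remainder after the last
digitized time.

Guarantees, verified in the tests: the recomputed KM matches the input
coordinates within 1/n wherever integer granularity allows (in the
censoring-thinned tail the binding limit is one event among the local
at-risk count); a simulate → digitize → reconstruct → refit round trip
recovers the generating parameters within ~5% at n = 5,000 and ~10% at
n = 500; bounded digitization jitter of ±0.01 propagates to at most ~0.02
error in the reconstructed curve. Reconstruction quality degrades if the
digitized grid is as coarse as the at-risk row — trace the curve densely
(the synthetic digitizer exposes `risk_grid` separately for this reason).

## Cohort engine

Three states (progression-free, progressed, dead) on 6-week cycles
(42 days; months of 30.4375 days; all conversions centralised in
`units.py`). The default trace is partitioned-survival: occupancy read
directly off the OS/PFS curves at cycle boundaries, with PFS clamped to
never exceed OS. An explicit transition-probability recursion (per-cycle
conditional probabilities from the same curves) is available as
`trace_mode="transition"` for comparison; the two agree on life-years to
a few percent.

Background mortality uses an annual life table as a piecewise-constant
hazard, combined multiplicatively with disease survival (additive
hazards). Ages past the table reuse the terminal row. The packaged table
is synthetic-but-realistic (Gompertz-calibrated, q ≈ 1.1% at age 64,
≈ 4.7% at 80, ages 50–100); a national table can be substituted from a
2-column file without code changes.

Defaults where the source analysis printed none: cohort start age 64
(typical of the trial population); "lifetime" operationalised as 20 years
or an alive fraction below 0.1%, whichever comes first (the 20-year cap
binds here; ~1% of the chemotherapy cohort is alive at 20 years). Both
are `ModelSettings` fields.

Half-cycle correction averages each cycle's start and end occupancy.
Discounting is 3%/year applied at cycle-start times, `(1+r)^(−t_years)`.

**Outcome conventions.** Costs and QALYs are discounted. Life-years are
reported undiscounted (the discounted total is kept in the result
breakdown). This convention — common in published oncology models, where
the per-LY ratio is quoted against undiscounted life expectancy — is part
of the structural calibration below.

## Economics

Drug acquisition is priced per mg (printed per-unit prices divided by the
unit size; no vial rounding) with doses resolved by body weight
(3 mg/kg nivolumab q2w, 1 mg/kg ipilimumab q6w) or body surface area
(pemetrexed 500 mg/m², cisplatin 75 mg/m², gemcitabine 1250 mg/m², q3w,
four induction doses; pemetrexed maintenance thereafter for the
nonsquamous fraction). The reference patient is 70 kg / 1.86 m². A
`max_doses`/`first_cycle` mechanism implements induction caps and
maintenance switches; fractional components implement the histology mix
(squamous fraction 0.30 by default, configurable and sensitivity-tested —
squamous patients receive the far cheaper gemcitabine doublet and no
maintenance).

Administration follows the Medicare infusion schedule: first hour
$143.08, each additional hour $30.99; one hour per antibody infusion, a
single 2-hour visit per chemotherapy doublet administration.

Adverse events (diarrhea, rash, fatigue, nausea, anemia, neutropenia) are
applied once at model entry as incidence-weighted management costs and
utility decrements lasting one cycle — the standard simplification when
durations are unreported; both magnitudes are configurable.

Second-line ("subsequent") therapy: the default costs the printed per-arm
amounts ($1,858 combination, $8,448 chemotherapy) **per cycle spent in
the progressed state**, treating them as expected per-cycle amounts for
the whole progressed cohort (i.e. already weighted by the 44%/56% uptake
reported for the arms). A one-time-at-progression mode and explicit
uptake proportions are available (`subsequent_mode`,
`subsequent_proportion`) — the `subsequent_therapy_cost` primitive takes
the proportion explicitly.

First-line treatment runs until progression, capped at 17 cycles
(≈ 2 years), mirroring the underlying trial protocol's immunotherapy
stopping rule; set `treatment_cap_cycles=None` for treat-to-progression
without a cap.

## Structural calibration

Several structural conventions are never printed in publications of this
kind (the HR application rule, the second-line costing mode, the
LY-discounting convention, the stopping rule, the histology mix). The
defaults above were selected by checking each documented switch
combination against the published base-case table and keeping the one
that reproduces it: all eight base-case quantities agree within ±10%
(ICER −2.1%, per-LY ratio +0.3%), the three subgroup ICERs within ±7%,
and the acceptability probabilities within ~2 percentage points. Changing
any single switch moves the incremental cost by 20–40% — which is exactly
why they are explicit configuration fields rather than buried constants.

## Sensitivity analyses

*One-way (tornado):* each parameter with distinct bounds is set to its
low and high value with the rest at baseline; rows are ranked by the
absolute ICER swing. Bounds are the published minimum/maximum columns
(mostly ±20% of baseline; weight 60–140 kg; HR 95% CIs). The discount
rate is varied ±20% (0.024–0.036) in the tornado but held fixed in the
PSA, like the survival-model parameters (no published distribution).

*Probabilistic:* every distributional parameter is drawn independently —
beta for probabilities, incidences and utilities (moment-matched to the
baseline mean and the printed SD, or range/4 when no SD is given;
infeasible moments fall back to a bounded uniform), lognormal for costs
and fees (moment-matched, SD = range/4), normal for weight
(SD = range/3.92, i.e. bounds read as a 95% interval), and normal on the
log scale for hazard ratios (SD = (log hi − log lo)/3.92) to guarantee
positivity. Disutilities are sampled on magnitude and re-negated. Draws
are clamped to admissible domains (probabilities to [0,1], positives
> 0). n = 1,000 draws by default, seed 227; a fixed seed gives
bit-identical results. The CEAC reports the fraction of draws with
positive net monetary benefit, NMB = λ·ΔQALY − ΔCost, over a $0–$300,000
grid in $5,000 steps.

*Subgroups:* PD-L1 ≥1%, ≥50% and <1% re-run the full pipeline with the
subgroup OS/PFS hazard ratios substituted and everything else unchanged;
an optional per-subgroup PSA attaches acceptability values.

## Synthetic data

The generator exists so the whole pipeline runs and is tested without any
external data. It emulates: inverse-CDF event times from known
log-logistic truths (with the HR applied on the configured scale);
independent uniform administrative censoring with the horizon calibrated
by bisection to hit the requested censored fraction; digitization as
step-interpolation of the KM estimate on a grid with optional bounded
uniform jitter; and at-risk rows on a (typically sparser) grid. What it
does **not** emulate: digitization error that is correlated along the
curve (a human tracing error drifts rather than jitters), informative
censoring, delayed treatment effects or crossing hazards, and
patient-level heterogeneity in weight/BSA (the cohort uses a single
reference patient). Passing tests therefore demonstrate internal
consistency of the reconstruction/fitting/engine machinery, not fidelity
of any specific published curve.

## Numerical choices and degenerate inputs

Survival evaluation uses `logaddexp` for stability at extreme times;
interval event probabilities are clipped to [0,1] and raise if the
interval start has zero survival. Trace rows are validated to sum to 1
within 1e-9 and death occupancy to be nondecreasing. Event
apportionment uses largest-remainder/running-sum rounding so integer
totals are conserved. The ICER computation flags dominance and returns an
undefined signal (not a crash) when the QALY difference is below 1e-12.
Fits require ≥2 events; all-censored input raises. Problem sizes in the
test suite (n = 200–5,000 subjects for reconstruction/fitting checks,
1,000 PSA draws, 173-cycle horizon) keep the full suite and the
acceptance script each under a minute while leaving Monte-Carlo error
well inside the asserted tolerances.

## Known limitations

- Cohort-level (no microsimulation); a single reference patient's
  weight/BSA scales all dosing.
- Constant hazard ratios over the whole horizon; no treatment-effect
  waning, no cure fraction, no spline extrapolation.
- Adverse events are a one-off expected burden, not time-resolved.
- The packaged life table is synthetic (realistic but not a national
  statistic); substitute a real table for policy use.
- Prices are consumed as printed (no CPI machinery, no commercial
  reimbursement schedules).
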