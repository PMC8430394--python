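"""Costs and quality-adjusted outcomes for one treatment strategy.

Drug acquisition is priced per mg from average-wholesale-price unit costs,
with doses resolved by body weight (mg/kg), body surface area (mg/m2) or
flat amounts, and administration fees following the Medicare infusion
schedule (first hour + additional hours).  Adverse-event management costs
and disutilities are applied once at model entry, weighted by incidence.
Subsequent (second-line) therapy is costed either once at progression or
per cycle spent progressed, controlled by configuration.  Discounted
totals per arm feed the incremental cost-effectiveness ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .markov import CohortTrace, ModelSettings, discount_factor, half_cycle_correct

__all__ = [
    "DrugComponent",
    "InfusionVisit",
    "DosingRegimen",
    "PatientProfile",
    "AdverseEvent",
    "AdverseEventProfile",
    "EconomicInputs",
    "ArmResult",
    "ICERResult",
    "drug_cost_per_cycle",
    "administration_cost_per_cycle",
    "one_time_ae_burden",
    "subsequent_therapy_cost",
    "accumulate",
    "compute_icer",
]

DoseBasis = Literal["per_kg", "per_m2", "flat"]


@dataclass(frozen=True)
class DrugComponent:
    """One drug line of a regimen.

    ``fraction`` is the share of the cohort receiving the component (used
    for histology-specific chemotherapy); ``first_cycle`` delays the start
    (pemetrexed maintenance begins once the four induction doses are done);
    ``max_doses`` caps the cumulative administrations.
    """

    name: str
    dose: float
    basis: DoseBasis
    interval_weeks: float
    max_doses: int | None = None
    first_cycle: int = 0
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.dose < 0 or self.interval_weeks <= 0:
            raise ValueError("dose must be >= 0 and interval positive")
        if not (0 <= self.fraction <= 1):
            raise ValueError("fraction must lie in [0, 1]")

    def doses_in_cycle(self, cycle_index: int, cycle_weeks: float = 6.0) -> float:
        if cycle_index < self.first_cycle:
            return 0.0
        per_cycle = cycle_weeks / self.interval_weeks
        if self.max_doses is None:
            return per_cycle
        done = (cycle_index - self.first_cycle) * per_cycle
        return float(np.clip(self.max_doses - done, 0.0, per_cycle))

    def dose_mg(self, profile: "PatientProfile") -> float:
        if self.basis == "per_kg":
            return self.dose * profile.weight_kg
        if self.basis == "per_m2":
            return self.dose * profile.bsa_m2
        return self.dose


@dataclass(frozen=True)
class InfusionVisit:
    """An infusion-chair visit schedule (hours billed per visit)."""

    hours: float
    interval_weeks: float
    max_visits: int | None = None
    first_cycle: int = 0
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.hours < 1:
            raise ValueError("an infusion visit is billed at least one hour")

    def visits_in_cycle(self, cycle_index: int, cycle_weeks: float = 6.0) -> float:
        if cycle_index < self.first_cycle:
            return 0.0
        per_cycle = cycle_weeks / self.interval_weeks
        if self.max_visits is None:
            return per_cycle
        done = (cycle_index - self.first_cycle) * per_cycle
        return float(np.clip(self.max_visits - done, 0.0, per_cycle))


@dataclass(frozen=True)
class DosingRegimen:
    components: tuple[DrugComponent, ...]
    visits: tuple[InfusionVisit, ...] = ()
    treatment_cap_cycles: int | None = None  # optional stopping rule

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "visits", tuple(self.visits))


@dataclass(frozen=True)
class PatientProfile:
    weight_kg: float = 70.0
    bsa_m2: float = 1.86
    squamous_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.bsa_m2 <= 0:
            raise ValueError("weight and BSA must be positive")
        if not (0 <= self.squamous_fraction <= 1):
            raise ValueError("squamous fraction must lie in [0, 1]")


@dataclass(frozen=True)
class AdverseEvent:
    name: str
    incidence: float
    cost: float
    disutility: float  # <= 0

    def __post_init__(self) -> None:
        if not (0 <= self.incidence <= 1):
            raise ValueError(f"{self.name}: incidence must lie in [0, 1]")
        if self.cost < 0:
            raise ValueError(f"{self.name}: cost must be nonnegative")
        if self.disutility > 0:
            raise ValueError(f"{self.name}: disutility must be <= 0")


@dataclass(frozen=True)
class AdverseEventProfile:
    events: tuple[AdverseEvent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))


@dataclass(frozen=True)
class EconomicInputs:
    """Unit prices and value parameters shared by the cost calculations."""

    prices_per_mg: dict[str, float]
    admin_first_hour: float = 143.08
    admin_additional_hour: float = 30.99
    subsequent_cost: float = 0.0
    subsequent_proportion: float = 0.0
    subsequent_mode: Literal["one_time", "per_cycle"] = "one_time"
    utility_pfs: float = 0.71
    utility_pd: float = 0.67

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.prices_per_mg.values()):
            raise ValueError("prices must be nonnegative")
        if not (0 <= self.utility_pfs <= 1 and 0 <= self.utility_pd <= 1):
            raise ValueError("utilities must lie in [0, 1]")
        if not (0 <= self.subsequent_proportion <= 1):
            raise ValueError("subsequent-therapy proportion must lie in [0, 1]")

    def price(self, drug: str) -> float:
        try:
            return self.prices_per_mg[drug]
        except KeyError:
            raise KeyError(f"no unit price configured for drug {drug!r}") from None


@dataclass(frozen=True)
class ArmResult:
    """Totals for one strategy.

    Costs and QALYs are discounted; ``life_years`` is the undiscounted
    life expectancy (the convention under which the published per-LY
    ratios are reported).  The discounted life-year total is kept in
    ``breakdown['life_years_discounted']``.
    """

    cost: float
    life_years: float
    qalys: float
    breakdown: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.qalys > self.life_years + 1e-9:
            raise ValueError("QALYs cannot exceed life-years")


@dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_qaly: float | None
    icer_per_ly: float | None
    dominance: str  # "", "intervention_dominant", "intervention_dominated", "indeterminate"


def drug_cost_per_cycle(
    regimen: DosingRegimen,
    profile: PatientProfile,
    econ: EconomicInputs,
    cycle_index: int,
    cycle_weeks: float = 6.0,
) -> float:
    """Acquisition cost of all regimen components billed in one cycle."""
    total = 0.0
    for comp in regimen.components:
        n = comp.doses_in_cycle(cycle_index, cycle_weeks)
        if n <= 0:
            continue
        total += comp.dose_mg(profile) * econ.price(comp.name) * n * comp.fraction
    return total


def administration_cost_per_cycle(
    regimen: DosingRegimen,
    econ: EconomicInputs,
    cycle_index: int,
    cycle_weeks: float = 6.0,
) -> float:
    """Infusion fees: first hour plus additional hours, per visit."""
    total = 0.0
    for visit in regimen.visits:
        n = visit.visits_in_cycle(cycle_index, cycle_weeks)
        if n <= 0:
            continue
        per_visit = econ.admin_first_hour + (visit.hours - 1.0) * econ.admin_additional_hour
        total += per_visit * n * visit.fraction
    return total


def one_time_ae_burden(
    profile: AdverseEventProfile, cycle_years: float
) -> tuple[float, float]:
    """Expected (cost, QALY loss) of treatment-related adverse events.

    Incidence-weighted management cost and a utility decrement lasting one
    model cycle, both charged once at model entry.
    """
    cost = sum(ae.incidence * ae.cost for ae in profile.events)
    qaly_loss = sum(ae.incidence * abs(ae.disutility) for ae in profile.events) * cycle_years
    return cost, qaly_loss


def subsequent_therapy_cost(
    econ: EconomicInputs, newly_progressed_mass: float
) -> float:
    """One-time second-line cost for the cohort mass progressing this cycle."""
    if not (0 <= newly_progressed_mass <= 1):
        raise ValueError("progressed mass must lie in [0, 1]")
    return newly_progressed_mass * econ.subsequent_proportion * econ.subsequent_cost


def accumulate(
    trace: CohortTrace,
    econ: EconomicInputs,
    ae: AdverseEventProfile,
    regimen: DosingRegimen,
    settings: ModelSettings,
    profile: PatientProfile | None = None,
) -> ArmResult:
    """Discounted cost, life-years and QALYs for one arm.

    First-line drug and administration costs accrue while the cohort is
    progression-free (treatment until progression, optionally capped);
    subsequent-therapy costs at or after progression per the configured
    mode; adverse-event burden once at entry.
    """
    profile = profile or PatientProfile()
    if settings.half_cycle_correction:
        occ = half_cycle_correct(trace)
    else:
        occ = trace.to_frame().iloc[:-1].reset_index(drop=True)
    n = len(occ)
    k = np.arange(n)
    disc = discount_factor(settings, k)
    cyc_years = settings.cycle_years
    cycle_weeks = settings.cycle_days / 7.0

    pfs = occ["pfs"].to_numpy()
    pd_occ = occ["pd"].to_numpy()

    alive = pfs + pd_occ
    ly = float(np.sum(alive * cyc_years))
    ly_disc = float(np.sum(alive * cyc_years * disc))
    qaly_states = float(
        np.sum((pfs * econ.utility_pfs + pd_occ * econ.utility_pd) * cyc_years * disc)
    )
    ae_cost, ae_qaly_loss = one_time_ae_burden(ae, cyc_years)
    qaly = max(qaly_states - ae_qaly_loss, 0.0)

    on_treat = pfs.copy()
    if regimen.treatment_cap_cycles is not None:
        on_treat[regimen.treatment_cap_cycles :] = 0.0
    drug = float(
        sum(
            on_treat[i] * drug_cost_per_cycle(regimen, profile, econ, i, cycle_weeks) * disc[i]
            for i in range(n)
        )
    )
    admin = float(
        sum(
            on_treat[i]
            * administration_cost_per_cycle(regimen, econ, i, cycle_weeks)
            * disc[i]
            for i in range(n)
        )
    )

    if econ.subsequent_mode == "per_cycle":
        subseq = float(
            np.sum(pd_occ * econ.subsequent_proportion * econ.subsequent_cost * disc)
        )
    else:
        # one-time at progression: mass leaving PFS this cycle (boundary drop)
        inflow = np.maximum(-np.diff(trace.pfs), 0.0)[:n]
        subseq = float(
            np.sum(inflow * econ.subsequent_proportion * econ.subsequent_cost * disc)
        )

    cost = drug + admin + ae_cost + subseq
    return ArmResult(
        cost=cost,
        life_years=ly,
        qalys=qaly,
        breakdown={
            "drug": drug,
            "administration": admin,
            "adverse_events": ae_cost,
            "subsequent_therapy": subseq,
            "ae_qaly_loss": ae_qaly_loss,
            "life_years_discounted": ly_disc,
        },
    )


def compute_icer(intervention: ArmResult, comparator: ArmResult) -> ICERResult:
    """Incremental cost per QALY (and per LY), with dominance flags."""
    dc = intervention.cost - comparator.cost
    dly = intervention.life_years - comparator.life_years
    dq = intervention.qalys - comparator.qalys

    if abs(dq) < 1e-12:
        dominance = "indeterminate"
        icer_q = None
    elif dc <= 0 and dq > 0:
        dominance = "intervention_dominant"
        icer_q = dc / dq
    elif dc > 0 and dq < 0:
        dominance = "intervention_dominated"
        icer_q = None
    else:
        dominance = ""
        icer_q = dc / dq
    icer_ly = dc / dly if abs(dly) > 1e-12 else None
    return ICERResult(dc, dly, dq, icer_q, icer_ly, dominance)
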