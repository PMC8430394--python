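"""Decision analyses on top of the cohort model.

Provides the deterministic base case, one-way (tornado) sensitivity
analysis over the configured parameter bounds, probabilistic sensitivity
analysis with cost-effectiveness acceptability curves, and subgroup
re-runs that substitute subgroup-specific hazard ratios while keeping all
other inputs fixed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import ARMS, ModelConfig, chemo_regimen, nivo_regimen, Param
from .economics import (
    AdverseEvent,
    AdverseEventProfile,
    ArmResult,
    EconomicInputs,
    ICERResult,
    PatientProfile,
    accumulate,
    compute_icer,
)
from .markov import build_trace
from .survival import SurvivalCurve

__all__ = [
    "ParameterSpec",
    "SubgroupSpec",
    "BaseCaseResult",
    "PSAResult",
    "evaluate_arm",
    "run_base_case",
    "one_way_dsa",
    "build_parameter_specs",
    "draw_parameters",
    "run_psa",
    "run_subgroup",
    "WTP_GRID",
]

# willingness-to-pay grid for acceptability curves, USD per QALY
WTP_GRID = np.arange(0, 300_001, 5_000, dtype=float)


@dataclass(frozen=True)
class ParameterSpec:
    """Sampling/bounds spec for one uncertain parameter."""

    name: str
    value: float
    low: float
    high: float
    dist: str
    sd: float | None = None


@dataclass(frozen=True)
class SubgroupSpec:
    """A PD-L1 expression subgroup defined by its own OS/PFS hazard ratios."""

    label: str
    os_hr: float
    pfs_hr: float
    os_hr_ci: tuple[float, float] | None = None
    pfs_hr_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.os_hr <= 0 or self.pfs_hr <= 0:
            raise ValueError("subgroup hazard ratios must be positive")


@dataclass(frozen=True)
class BaseCaseResult:
    nivo: ArmResult
    chemo: ArmResult
    icer: ICERResult

    def summary(self) -> pd.DataFrame:
        rows = []
        for label, arm in (("nivolumab+ipilimumab", self.nivo), ("chemotherapy", self.chemo)):
            rows.append(
                {
                    "strategy": label,
                    "cost": arm.cost,
                    "life_years": arm.life_years,
                    "qalys": arm.qalys,
                }
            )
        return pd.DataFrame(rows)


def evaluate_arm(config: ModelConfig, arm: str, values: dict[str, float]) -> ArmResult:
    """Run one arm of the model under a fully resolved parameter map."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    settings = replace(config.settings, discount_rate=values["discount_rate"])

    if arm == "nivo":
        os_curve = SurvivalCurve(config.os_baseline, values["os_hr"], config.hr_mode)
        pfs_curve = SurvivalCurve(config.pfs_baseline, values["pfs_hr"], config.hr_mode)
        regimen = nivo_regimen(config.treatment_cap_cycles)
    else:
        os_curve = SurvivalCurve(config.os_baseline)
        pfs_curve = SurvivalCurve(config.pfs_baseline)
        regimen = chemo_regimen(config.squamous_fraction)

    profile = PatientProfile(
        weight_kg=values["weight"],
        bsa_m2=config.bsa_m2,
        squamous_fraction=config.squamous_fraction,
    )
    econ = EconomicInputs(
        prices_per_mg={
            d: values[f"price.{d}"] / mg for d, mg in config.unit_mg.items()
        },
        admin_first_hour=values["admin_first_hour"],
        admin_additional_hour=values["admin_additional_hour"],
        subsequent_cost=values[f"subsequent_cost.{arm}"],
        subsequent_proportion=config.subsequent_proportion[arm],
        subsequent_mode=config.subsequent_mode,
        utility_pfs=min(values["utility_pfs"], 1.0),
        utility_pd=min(values["utility_pd"], 1.0),
    )
    ae = AdverseEventProfile(
        tuple(
            AdverseEvent(
                name,
                float(np.clip(values[f"ae_incidence.{arm}.{name}"], 0.0, 1.0)),
                max(values[f"ae_cost.{name}"], 0.0),
                min(values[f"ae_disutility.{name}"], 0.0),
            )
            for name in config.ae_names
        )
    )
    trace = build_trace(os_curve, pfs_curve, config.life_table, settings)
    return accumulate(trace, econ, ae, regimen, settings, profile)


def _evaluate_pair(config: ModelConfig, values: dict[str, float]) -> tuple[ArmResult, ArmResult]:
    return evaluate_arm(config, "nivo", values), evaluate_arm(config, "chemo", values)


def run_base_case(config: ModelConfig) -> BaseCaseResult:
    """Deterministic run of both strategies at baseline parameter values."""
    nivo, chemo = _evaluate_pair(config, config.baseline_values())
    return BaseCaseResult(nivo, chemo, compute_icer(nivo, chemo))


def build_parameter_specs(config: ModelConfig) -> list[ParameterSpec]:
    """One spec per parameter whose bounds actually vary."""
    return [
        ParameterSpec(name, p.value, p.low, p.high, p.dist, p.sd)
        for name, p in sorted(config.parameters.items())
        if p.varies
    ]


def one_way_dsa(
    config: ModelConfig, specs: list[ParameterSpec] | None = None
) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low and high bound.

    All other parameters stay at baseline.  Rows are sorted by the ICER
    swing |high - low|, descending; parameters with no effect rank last.
    """
    specs = build_parameter_specs(config) if specs is None else specs
    base_values = config.baseline_values()
    rows = []
    for spec in specs:
        icers = {}
        for side in ("low", "high"):
            values = dict(base_values)
            values[spec.name] = getattr(spec, side)
            nivo, chemo = _evaluate_pair(config, values)
            res = compute_icer(nivo, chemo)
            icers[side] = res.icer_per_qaly if res.icer_per_qaly is not None else np.nan
        swing = abs(icers["high"] - icers["low"])
        rows.append(
            {
                "parameter": spec.name,
                "low": spec.low,
                "high": spec.high,
                "icer_at_low": icers["low"],
                "icer_at_high": icers["high"],
                "swing": swing,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("swing", ascending=False, kind="stable").reset_index(drop=True)


def _beta_from_moments(mean: float, sd: float) -> tuple[float, float] | None:
    if not (0 < mean < 1) or sd <= 0:
        return None
    var = sd * sd
    if var >= mean * (1 - mean):
        return None  # infeasible moments
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def draw_parameters(
    specs: list[ParameterSpec], rng: np.random.Generator
) -> dict[str, float]:
    """One random draw of every uncertain parameter.

    Normal uses SD = range/3.92 (bounds read as a 95% interval); hazard
    ratios are normal on the log scale; beta and lognormal are
    moment-matched to the baseline mean with SD = printed SD or range/4.
    Infeasible beta moments fall back to a uniform draw over the bounds.
    Negative-valued parameters (disutilities) are sampled on magnitude.
    """
    out: dict[str, float] = {}
    for spec in specs:
        if not spec.high > spec.low:
            out[spec.name] = spec.value
            continue
        sign = -1.0 if spec.value < 0 or (spec.value == 0 and spec.high <= 0) else 1.0
        mean = abs(spec.value)
        lo, hi = sorted((abs(spec.low), abs(spec.high)))
        rng_sd = spec.sd if spec.sd is not None else (hi - lo) / 4.0

        if spec.dist == "normal":
            draw = rng.normal(mean, (hi - lo) / 3.92)
            draw = max(draw, 1e-9)
        elif spec.dist == "loghr_normal":
            sd_log = (np.log(hi) - np.log(lo)) / 3.92
            draw = float(np.exp(rng.normal(np.log(mean), sd_log)))
        elif spec.dist == "beta":
            ab = _beta_from_moments(mean, rng_sd)
            draw = rng.beta(*ab) if ab is not None else rng.uniform(lo, hi)
        elif spec.dist == "lognormal":
            cv = rng_sd / mean if mean > 0 else 0.0
            if cv <= 0:
                draw = mean
            else:
                sigma2 = np.log1p(cv * cv)
                mu = np.log(mean) - sigma2 / 2.0
                draw = float(rng.lognormal(mu, np.sqrt(sigma2)))
        elif spec.dist == "fixed":
            draw = mean
        else:  # pragma: no cover - guarded by Param validation
            raise ValueError(f"unknown distribution {spec.dist!r}")
        out[spec.name] = sign * draw
    return out


@dataclass(frozen=True)
class PSAResult:
    samples: pd.DataFrame  # delta_cost, delta_qaly, delta_ly per draw
    wtp_grid: np.ndarray
    ceac: np.ndarray  # P(intervention cost-effective) at each WTP

    def acceptability_at(self, wtp: float) -> float:
        nmb = wtp * self.samples["delta_qaly"] - self.samples["delta_cost"]
        return float((nmb > 0).mean())

    def ceac_table(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "p_cost_effective": self.ceac})


def run_psa(
    config: ModelConfig,
    n_iterations: int = 1000,
    seed: int = 227,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Monte-Carlo probabilistic sensitivity analysis.

    Draws every distributional parameter `n_iterations` times, re-runs both
    arms per draw, and summarises acceptability over the WTP grid.
    Structural parameters (survival-model scale/shape, cycle length,
    horizon) stay fixed.  Reproducible under a fixed seed.
    """
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    wtp = WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    # only parameters with a sampling distribution vary in the PSA
    specs = [s for s in build_parameter_specs(config) if s.dist != "fixed"]
    base_values = config.baseline_values()
    rng = np.random.default_rng(seed)

    recs = []
    for _ in range(n_iterations):
        values = dict(base_values)
        values.update(draw_parameters(specs, rng))
        nivo, chemo = _evaluate_pair(config, values)
        recs.append(
            {
                "delta_cost": nivo.cost - chemo.cost,
                "delta_qaly": nivo.qalys - chemo.qalys,
                "delta_ly": nivo.life_years - chemo.life_years,
            }
        )
    samples = pd.DataFrame(recs)
    nmb = wtp[:, None] * samples["delta_qaly"].to_numpy() - samples["delta_cost"].to_numpy()
    ceac = (nmb > 0).mean(axis=1)
    return PSAResult(samples, wtp, ceac)


@dataclass(frozen=True)
class SubgroupResult:
    spec: SubgroupSpec
    base: BaseCaseResult
    psa: PSAResult | None

    @property
    def icer_per_qaly(self) -> float | None:
        return self.base.icer.icer_per_qaly


def run_subgroup(
    config: ModelConfig,
    sub: SubgroupSpec,
    psa_iterations: int = 0,
    seed: int = 227,
) -> SubgroupResult:
    """Re-run the pipeline with subgroup hazard ratios, all else unchanged."""
    os_p = config.parameters["os_hr"]
    pfs_p = config.parameters["pfs_hr"]
    os_ci = sub.os_hr_ci or (sub.os_hr, sub.os_hr)
    pfs_ci = sub.pfs_hr_ci or (sub.pfs_hr, sub.pfs_hr)
    sub_config = config.with_hrs(
        os_hr=Param(sub.os_hr, os_ci[0], os_ci[1], os_p.dist),
        pfs_hr=Param(sub.pfs_hr, pfs_ci[0], pfs_ci[1], pfs_p.dist),
    )
    base = run_base_case(sub_config)
    psa = run_psa(sub_config, psa_iterations, seed) if psa_iterations > 0 else None
    return SubgroupResult(sub, base, psa)
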