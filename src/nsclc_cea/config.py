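"""Model configuration: every input parameter with its uncertainty spec.

A :class:`ModelConfig` carries the structural settings (cycle length,
horizon, discounting, hazard-ratio convention, life table) plus a flat
dictionary of named :class:`Param` entries — baseline value, low/high
bounds and distribution family — mirroring a published parameter table.
The same object drives the deterministic base case, the one-way
sensitivity analysis (low/high bounds) and the probabilistic sensitivity
analysis (distributions).  Round-trips to YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .economics import DosingRegimen, DrugComponent, InfusionVisit
from .markov import LifeTable, ModelSettings
from .survival import LogLogisticParams

__all__ = ["Param", "ModelConfig", "nivo_regimen", "chemo_regimen"]

ARMS = ("nivo", "chemo")


@dataclass(frozen=True)
class Param:
    """A model input with its deterministic bounds and PSA distribution.

    ``dist`` is one of ``fixed``, ``normal``, ``lognormal``, ``beta`` or
    ``loghr_normal`` (normal on the log scale, used for hazard ratios).
    ``sd`` optionally pins the sampling standard deviation; otherwise it is
    derived from the bounds.
    """

    value: float
    low: float | None = None
    high: float | None = None
    dist: str = "fixed"
    sd: float | None = None

    def __post_init__(self) -> None:
        lo = self.value if self.low is None else self.low
        hi = self.value if self.high is None else self.high
        object.__setattr__(self, "low", lo)
        object.__setattr__(self, "high", hi)
        if not (min(lo, hi) <= self.value <= max(lo, hi)):
            raise ValueError(
                f"baseline {self.value} outside bounds [{lo}, {hi}]"
            )
        if self.dist not in ("fixed", "normal", "lognormal", "beta", "loghr_normal"):
            raise ValueError(f"unknown distribution {self.dist!r}")

    @property
    def varies(self) -> bool:
        return self.low != self.high


@dataclass(frozen=True)
class ModelConfig:
    """Complete input set for a two-arm cost-effectiveness run."""

    os_baseline: LogLogisticParams
    pfs_baseline: LogLogisticParams
    parameters: dict[str, Param]
    life_table: LifeTable
    settings: ModelSettings = ModelSettings()
    ae_names: tuple[str, ...] = ()
    unit_mg: dict[str, float] = field(default_factory=dict)
    bsa_m2: float = 1.86
    squamous_fraction: float = 0.0
    subsequent_proportion: dict[str, float] = field(
        default_factory=lambda: {"nivo": 0.44, "chemo": 0.56}
    )
    subsequent_mode: str = "per_cycle"  # or "one_time"
    hr_mode: str = "ph"  # or "aft"
    treatment_cap_cycles: int | None = None

    def __post_init__(self) -> None:
        missing = [k for k in self.required_names() if k not in self.parameters]
        if missing:
            raise ValueError(f"config missing parameters: {missing}")

    def required_names(self) -> list[str]:
        names = [
            "os_hr",
            "pfs_hr",
            "weight",
            "utility_pfs",
            "utility_pd",
            "admin_first_hour",
            "admin_additional_hour",
            "discount_rate",
        ]
        names += [f"price.{d}" for d in self.unit_mg]
        names += [f"subsequent_cost.{arm}" for arm in ARMS]
        for ae in self.ae_names:
            names += [
                f"ae_incidence.nivo.{ae}",
                f"ae_incidence.chemo.{ae}",
                f"ae_cost.{ae}",
                f"ae_disutility.{ae}",
            ]
        return names

    def baseline_values(self) -> dict[str, float]:
        return {k: p.value for k, p in self.parameters.items()}

    def with_params(self, **updates: Param) -> "ModelConfig":
        params = dict(self.parameters)
        params.update(updates)
        return replace(self, parameters=params)

    def with_hrs(self, os_hr: Param, pfs_hr: Param) -> "ModelConfig":
        return self.with_params(os_hr=os_hr, pfs_hr=pfs_hr)

    # ---------------------------------------------------------------- YAML
    def to_dict(self) -> dict:
        return {
            "os_baseline": dataclasses.asdict(self.os_baseline),
            "pfs_baseline": dataclasses.asdict(self.pfs_baseline),
            "settings": dataclasses.asdict(self.settings),
            "life_table": {
                "ages": [float(a) for a in self.life_table.ages],
                "qx": [float(q) for q in self.life_table.qx],
            },
            "ae_names": list(self.ae_names),
            "unit_mg": dict(self.unit_mg),
            "bsa_m2": self.bsa_m2,
            "squamous_fraction": self.squamous_fraction,
            "subsequent_proportion": dict(self.subsequent_proportion),
            "subsequent_mode": self.subsequent_mode,
            "hr_mode": self.hr_mode,
            "treatment_cap_cycles": self.treatment_cap_cycles,
            "parameters": {
                k: {f.name: getattr(p, f.name) for f in dataclasses.fields(Param)}
                for k, p in self.parameters.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            os_baseline=LogLogisticParams(**d["os_baseline"]),
            pfs_baseline=LogLogisticParams(**d["pfs_baseline"]),
            parameters={k: Param(**v) for k, v in d["parameters"].items()},
            life_table=LifeTable(d["life_table"]["ages"], d["life_table"]["qx"]),
            settings=ModelSettings(**d["settings"]),
            ae_names=tuple(d.get("ae_names", ())),
            unit_mg=dict(d.get("unit_mg", {})),
            bsa_m2=d.get("bsa_m2", 1.86),
            squamous_fraction=d.get("squamous_fraction", 0.0),
            subsequent_proportion=dict(d.get("subsequent_proportion", {})),
            subsequent_mode=d.get("subsequent_mode", "per_cycle"),
            hr_mode=d.get("hr_mode", "ph"),
            treatment_cap_cycles=d.get("treatment_cap_cycles"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def nivo_regimen(treatment_cap_cycles: int | None = None) -> DosingRegimen:
    """Nivolumab 3 mg/kg every 2 weeks plus ipilimumab 1 mg/kg every 6 weeks,
    continued while progression-free."""
    return DosingRegimen(
        components=(
            DrugComponent("nivolumab", 3.0, "per_kg", interval_weeks=2.0),
            DrugComponent("ipilimumab", 1.0, "per_kg", interval_weeks=6.0),
        ),
        visits=(
            InfusionVisit(hours=1.0, interval_weeks=2.0),  # nivolumab
            InfusionVisit(hours=1.0, interval_weeks=6.0),  # ipilimumab
        ),
        treatment_cap_cycles=treatment_cap_cycles,
    )


def chemo_regimen(squamous_fraction: float) -> DosingRegimen:
    """Platinum doublet every 3 weeks for up to four doses.

    Nonsquamous: pemetrexed 500 mg/m2 + cisplatin 75 mg/m2, then pemetrexed
    maintenance until progression.  Squamous: gemcitabine 1250 mg/m2 +
    cisplatin 75 mg/m2, four doses at most.  Components are weighted by the
    cohort's histology mix.
    """
    sq = squamous_fraction
    nsq = 1.0 - sq
    return DosingRegimen(
        components=(
            DrugComponent("pemetrexed", 500.0, "per_m2", 3.0, max_doses=4, fraction=nsq),
            DrugComponent("gemcitabine", 1250.0, "per_m2", 3.0, max_doses=4, fraction=sq),
            DrugComponent("cisplatin", 75.0, "per_m2", 3.0, max_doses=4),
            DrugComponent(
                "pemetrexed", 500.0, "per_m2", 3.0, first_cycle=2, fraction=nsq
            ),
        ),
        visits=(
            InfusionVisit(hours=2.0, interval_weeks=3.0, max_visits=4),  # doublet
            InfusionVisit(hours=1.0, interval_weeks=3.0, first_cycle=2, fraction=nsq),
        ),
    )
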