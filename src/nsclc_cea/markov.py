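"""Three-state cohort engine: progression-free, progressed, dead.

State occupancy over a lifetime horizon is read directly off the OS and
PFS curves (a partitioned-survival structure): at every cycle boundary

    PFS(t)   = S_pfs(t) * S_bg(t)
    Death(t) = 1 - S_os(t) * S_bg(t)
    PD(t)    = 1 - PFS(t) - Death(t)   (clamped at 0 if the curves cross)

where S_bg is other-cause survival from a background life table, combined
multiplicatively (additive hazards).  A transition-probability mode that
converts the same curves into per-cycle conditional probabilities and runs
an explicit state-transition recursion is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import units
from .survival import SurvivalCurve, interval_event_prob

__all__ = [
    "ModelSettings",
    "LifeTable",
    "CohortTrace",
    "background_survival",
    "build_trace",
    "half_cycle_correct",
    "discount_factor",
]


@dataclass(frozen=True)
class ModelSettings:
    """Global simulation settings.

    The horizon acts as a lifetime proxy: the trace stops at `horizon_years`
    or once the alive fraction falls below `alive_floor`, whichever comes
    first.
    """

    cycle_days: float = units.CYCLE_DAYS
    horizon_years: float = 20.0
    discount_rate: float = 0.03  # per year, applied to costs and outcomes
    start_age: float = 64.0
    half_cycle_correction: bool = True
    alive_floor: float = 1e-3
    trace_mode: Literal["partitioned", "transition"] = "partitioned"

    def __post_init__(self) -> None:
        if self.cycle_days <= 0:
            raise ValueError("cycle length must be positive")
        if not (0 <= self.discount_rate < 1):
            raise ValueError("discount rate must be in [0, 1)")
        if self.horizon_years <= 0:
            raise ValueError("horizon must be positive")
        if self.horizon_years * units.DAYS_PER_YEAR < self.cycle_days:
            raise ValueError("horizon shorter than one cycle")

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / units.DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / units.DAYS_PER_YEAR

    @property
    def n_cycles(self) -> int:
        return int(np.floor(self.horizon_years / self.cycle_years + 1e-9))


@dataclass(frozen=True)
class LifeTable:
    """Annual probability of death by single year of age."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.ages, dtype=float)
        q = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", a)
        object.__setattr__(self, "qx", q)
        if a.shape != q.shape or a.ndim != 1 or a.size == 0:
            raise ValueError("ages and qx must be equal-length 1-D arrays")
        if np.any(np.diff(a) != 1):
            raise ValueError("life-table ages must be contiguous single years")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("death probabilities must lie in [0, 1]")

    def annual_hazard(self, age: float) -> float:
        """Constant hazard within the year of age; terminal row extends beyond."""
        idx = int(np.clip(np.floor(age) - self.ages[0], 0, self.ages.size - 1))
        q = float(self.qx[idx])
        if q >= 1.0:
            return np.inf
        return -np.log1p(-q)

    @classmethod
    def from_file(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame({"age_years": self.ages, "annual_q": self.qx}).to_csv(
            path, index=False
        )


def background_survival(table: LifeTable, start_age: float, t_months) -> np.ndarray | float:
    """Other-cause survival to `t_months` for a subject aged `start_age` at t=0.

    Piecewise-constant hazard within each year of age; ages past the table
    end reuse the terminal row's hazard.
    """
    t = np.atleast_1d(np.asarray(t_months, dtype=float))
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    if start_age < table.ages[0]:
        raise ValueError("start age below life-table range")
    t_years = t / units.MONTHS_PER_YEAR
    max_t = float(t_years.max()) if t_years.size else 0.0
    # cumulative hazard at whole-year boundaries from the start age
    n_years = int(np.floor(start_age + max_t) - np.floor(start_age)) + 1
    bounds = np.concatenate([[0.0], np.minimum(
        np.floor(start_age) + np.arange(1, n_years + 1) - start_age, max_t
    )])
    bounds = np.maximum.accumulate(np.clip(bounds, 0.0, max_t))
    haz = np.array(
        [table.annual_hazard(np.floor(start_age) + k) for k in range(n_years)]
    )
    seg = np.diff(bounds)
    cum = np.concatenate([[0.0], np.cumsum(seg * haz)])
    ch = np.interp(t_years, bounds, cum)
    # np.interp is exact here because H is piecewise linear in t between bounds
    out = np.exp(-ch)
    return float(out[0]) if np.isscalar(t_months) else out


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy at each cycle boundary (column per state)."""

    times_months: np.ndarray  # cycle-boundary times, length n_cycles + 1
    pfs: np.ndarray
    pd_state: np.ndarray
    dead: np.ndarray

    def __post_init__(self) -> None:
        rows = self.pfs + self.pd_state + self.dead
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("trace rows must sum to 1")
        for arr in (self.pfs, self.pd_state, self.dead):
            if np.any((arr < -1e-12) | (arr > 1 + 1e-12)):
                raise ValueError("occupancies must lie in [0, 1]")
        if np.any(np.diff(self.dead) < -1e-12):
            raise ValueError("death occupancy must be nondecreasing")

    @property
    def n_cycles(self) -> int:
        return self.times_months.size - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.times_months,
                "pfs": self.pfs,
                "pd": self.pd_state,
                "dead": self.dead,
            }
        )

    def to_file(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_trace(
    os_curve: SurvivalCurve,
    pfs_curve: SurvivalCurve,
    table: LifeTable,
    settings: ModelSettings,
) -> CohortTrace:
    """Occupancy at every cycle boundary out to the lifetime horizon.

    PFS occupancy is clamped to never exceed overall survival (digitized
    curves can cross slightly in the tail).  The trace is truncated once the
    alive fraction drops below ``settings.alive_floor``.
    """
    n = settings.n_cycles
    t = np.arange(n + 1) * settings.cycle_months
    s_bg = np.atleast_1d(background_survival(table, settings.start_age, t))

    if settings.trace_mode == "partitioned":
        s_os = os_curve.survival(t) * s_bg
        s_pfs = np.minimum(pfs_curve.survival(t) * s_bg, s_os)
        pfs = s_pfs
        dead = 1.0 - s_os
        pd_occ = np.maximum(1.0 - pfs - dead, 0.0)
    else:
        pfs = np.empty(n + 1)
        pd_occ = np.empty(n + 1)
        dead = np.empty(n + 1)
        pfs[0], pd_occ[0], dead[0] = 1.0, 0.0, 0.0
        for k in range(n):
            t0, t1 = t[k], t[k + 1]
            bg = 1.0 - float(s_bg[k + 1] / s_bg[k]) if s_bg[k] > 0 else 1.0
            p_die = min(1.0, interval_event_prob(os_curve, t0, t1) + bg)
            p_prog = interval_event_prob(pfs_curve, t0, t1)
            p_leave_pfs = max(p_prog, p_die)
            pfs[k + 1] = pfs[k] * (1.0 - p_leave_pfs)
            pd_occ[k + 1] = max(
                pd_occ[k] + pfs[k] * max(p_leave_pfs - p_die, 0.0) - pd_occ[k] * p_die,
                0.0,
            )
            dead[k + 1] = 1.0 - pfs[k + 1] - pd_occ[k + 1]

    # truncate once effectively everyone has died
    alive = 1.0 - dead
    below = np.flatnonzero(alive < settings.alive_floor)
    if below.size and below[0] >= 2:
        end = below[0] + 1
        t, pfs, pd_occ, dead = t[:end], pfs[:end], pd_occ[:end], dead[:end]

    return CohortTrace(t, pfs, pd_occ, dead)


def half_cycle_correct(trace: CohortTrace) -> pd.DataFrame:
    """Per-cycle effective occupancy = mean of the cycle's start and end rows.

    Returns one row per cycle (one fewer than the boundary count) with the
    cycle start time attached.
    """
    if trace.n_cycles < 1:
        raise ValueError("need at least one full cycle")
    mid = lambda a: 0.5 * (a[:-1] + a[1:])
    return pd.DataFrame(
        {
            "time_months": trace.times_months[:-1],
            "pfs": mid(trace.pfs),
            "pd": mid(trace.pd_state),
            "dead": mid(trace.dead),
        }
    )


def discount_factor(settings: ModelSettings, cycle_index) -> np.ndarray | float:
    """(1 + r)^(-t) with t the cycle-start time in years."""
    k = np.asarray(cycle_index, dtype=float)
    if np.any(k < 0):
        raise ValueError("cycle index must be nonnegative")
    out = (1.0 + settings.discount_rate) ** (-(k * settings.cycle_years))
    return float(out) if np.isscalar(cycle_index) else out
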