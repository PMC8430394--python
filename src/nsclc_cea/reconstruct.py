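"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published survival curves only show the product-limit estimate; fitting a
parametric model needs event/censoring records.  This module rebuilds a
patient-level dataset that is consistent with the digitized survival
coordinates and, when available, the numbers-at-risk row printed under the
figure: within each at-risk interval the survival drop fixes the number of
events and the residual at-risk decrement is attributed to censoring.  The
round trip (reconstruct -> Kaplan-Meier) reproduces the digitized curve up
to integer rounding, i.e. within 1/n.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DigitizedCurve",
    "RiskTable",
    "PseudoIPD",
    "reconstruct_pseudo_ipd",
    "km_estimate",
]


@dataclass(frozen=True)
class DigitizedCurve:
    """Ordered (time months, survival probability) coordinates, starting at (0, 1)."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.shape != s.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times and survival must be equal-length 1-D arrays")
        if t[0] != 0 or abs(s[0] - 1.0) > 1e-12:
            raise ValueError("digitized curve must start at (0, 1)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-9):
            raise ValueError("digitized survival must be nonincreasing")

    @classmethod
    def from_file(cls, path: str | Path) -> "DigitizedCurve":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame({"time_months": self.times, "survival": self.survival}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk printed under a KM figure: (time months, count)."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_at_risk, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_at_risk", n)
        if t.shape != n.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("risk table needs >= 2 (time, count) rows")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(n < 0):
            raise ValueError("at-risk counts must be nonnegative")
        if np.any(np.diff(n) > 0):
            raise ValueError("at-risk counts cannot increase over time")

    @classmethod
    def from_file(cls, path: str | Path) -> "RiskTable":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame({"time_months": self.times, "n_at_risk": self.n_at_risk}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class PseudoIPD:
    """Patient-level records: time in months and event indicator (1=event)."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be equal-length 1-D arrays")
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        if not np.all(np.isin(e, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @classmethod
    def from_file(cls, path: str | Path) -> "PseudoIPD":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["event"].to_numpy())

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame({"time_months": self.times, "event": self.events}).to_csv(
            path, index=False
        )


def reconstruct_pseudo_ipd(
    curve: DigitizedCurve,
    risk: RiskTable | None = None,
    total_n: int | None = None,
) -> PseudoIPD:
    """Rebuild event/censoring records from a digitized curve.

    With a risk table, each inter-row interval is solved iteratively: a
    trial censoring count is spread uniformly over the interval, events at
    each digitized drop follow the product-limit relation against the
    running at-risk count and reconstructed KM level (running-sum rounding
    conserves totals), and the censoring count is adjusted until the
    at-risk count at the interval end matches the printed one.  Events sit
    at the digitized drop times.  Without a risk table, ``total_n`` must be
    given and censoring is assumed to occur only after the last digitized
    event (the degraded mode appropriate when a figure prints no numbers
    at risk).
    """
    if risk is None:
        if total_n is None:
            raise ValueError("need either a risk table or total_n")
        risk = RiskTable(
            np.array([0.0, curve.times[-1] + 1e-9]), np.array([total_n, 0])
        )
        degraded = True
    else:
        if curve.times[-1] < risk.times[-1] - 1e-9:
            raise ValueError("digitized curve must span the risk-table interval")
        degraded = False

    t_d, s_d = curve.times, curve.survival
    out_times: list[float] = []
    out_events: list[int] = []

    km_level = 1.0  # reconstructed KM value carried across intervals
    n_carry = int(risk.n_at_risk[0])

    for j in range(len(risk.times) - 1):
        lo, hi = risk.times[j], risk.times[j + 1]
        n_start = min(n_carry, int(risk.n_at_risk[j]))
        n_end = int(risk.n_at_risk[j + 1]) if not degraded else 0
        if n_start <= 0 or km_level <= 0:
            break
        # digitized drops inside (lo, hi]
        in_int = (t_d > lo) & (t_d <= hi)
        in_int &= np.concatenate([[False], np.diff(s_d) < 0])
        drop_times = t_d[in_int]
        drop_targets = s_d[in_int]

        def walk(n_cens: int):
            """Step events and censorings through the interval.

            Censor times are spread uniformly; at each digitized drop the
            event count follows the product-limit relation against the
            current reconstructed KM level and at-risk count.  Returns the
            allocation and the at-risk count left at the interval end.
            """
            cens_times = lo + (np.arange(1, n_cens + 1) / (n_cens + 1)) * (hi - lo)
            n = n_start
            level = km_level
            alloc = []
            cum_frac = cum_int = 0.0
            prev_t = lo
            for t_i, s_i in zip(drop_times, drop_targets):
                n -= int(((cens_times > prev_t) & (cens_times <= t_i)).sum())
                prev_t = t_i
                if n <= 0 or level <= 0:
                    alloc.append(0)
                    continue
                d_frac = min(max(n * (1.0 - s_i / level), 0.0), float(n))
                d = int(round(cum_frac + d_frac) - cum_int)
                d = min(max(d, 0), n)
                cum_frac += d_frac
                cum_int += d
                level *= 1.0 - d / n
                n -= d
                alloc.append(d)
            n -= int((cens_times > prev_t).sum())
            return alloc, cens_times, n, level

        # iterate the censoring count until the end-of-interval at-risk
        # count matches the printed one (the degraded mode censors nobody)
        n_cens = 0 if degraded else max(n_start - n_end, 0) // 2
        for _ in range(40):
            alloc, cens_times, n_left, level = walk(n_cens)
            if degraded:
                break
            adjust = n_left - n_end
            if adjust == 0:
                break
            n_cens = int(np.clip(n_cens + adjust, 0, n_start))
        for t_i, d_i in zip(drop_times, alloc):
            out_times.extend([float(t_i)] * int(d_i))
            out_events.extend([1] * int(d_i))
        out_times.extend(map(float, cens_times))
        out_events.extend([0] * len(cens_times))
        km_level = level
        n_carry = n_left

    # subjects still at risk at the end of follow-up are censored there
    n_used = len(out_times)
    n_total = int(risk.n_at_risk[0])
    if n_used < n_total:
        last_t = float(max(curve.times[-1], risk.times[-1]))
        out_times.extend([last_t] * (n_total - n_used))
        out_events.extend([0] * (n_total - n_used))

    order = np.argsort(out_times, kind="stable")
    return PseudoIPD(np.asarray(out_times)[order], np.asarray(out_events)[order])


def km_estimate(ipd: PseudoIPD) -> DigitizedCurve:
    """Product-limit survival estimate evaluated at the distinct event times.

    Ties between events and censorings at the same time follow the usual
    convention that events happen first (censored subjects at t are still at
    risk for events at t).
    """
    if len(ipd) == 0:
        raise ValueError("empty dataset")
    order = np.lexsort((1 - ipd.events, ipd.times))
    times = ipd.times[order]
    events = ipd.events[order]

    out_t = [0.0]
    out_s = [1.0]
    s = 1.0
    n_at_risk = len(ipd)
    i = 0
    n = times.size
    while i < n:
        t = times[i]
        d = 0
        c = 0
        while i < n and times[i] == t:
            if events[i] == 1:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / n_at_risk
            out_t.append(float(t))
            out_s.append(s)
        n_at_risk -= d + c
    return DigitizedCurve(np.asarray(out_t), np.maximum(np.asarray(out_s), 0.0))
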