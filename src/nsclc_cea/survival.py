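"""Parametric survival curves for extrapolating trial endpoints.

The chemotherapy (reference) arm is represented by a log-logistic survival
function under the scale/shape convention

    S(t) = 1 / (1 + (lambda * t)**gamma),      t in months,

whose median is 1/lambda.  The intervention arm is obtained by applying a
hazard ratio to the fitted baseline, either as proportional hazards
(S**HR, the default) or as an accelerated-failure-time time ratio
(S(HR * t)).  Maximum-likelihood fitting on right-censored records and AIC
ranking against exponential and Weibull comparators support the model
selection step of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "LogLogisticParams",
    "ExponentialParams",
    "WeibullParams",
    "TreatmentEffect",
    "SurvivalCurve",
    "loglogistic_survival",
    "loglogistic_hazard",
    "apply_hazard_ratio",
    "interval_event_prob",
    "fit_loglogistic_mle",
    "fit_exponential_mle",
    "fit_weibull_mle",
    "select_model_aic",
]

HRMode = Literal["ph", "aft"]


@dataclass(frozen=True)
class LogLogisticParams:
    """Scale/shape pair (lambda, gamma); median survival is 1/scale months."""

    scale: float  # lambda, 1/months
    shape: float  # gamma, dimensionless

    def __post_init__(self) -> None:
        if not (self.scale > 0 and self.shape > 0):
            raise ValueError("log-logistic scale and shape must be positive")

    n_params = 2

    def log_survival(self, t):
        t = np.asarray(t, dtype=float)
        t1 = np.atleast_1d(t)
        out = np.zeros_like(t1)
        pos = t1 > 0
        z = self.shape * (np.log(self.scale) + np.log(t1[pos]))
        out[pos] = -np.logaddexp(0.0, z)
        return out.reshape(t.shape)

    def survival(self, t):
        return np.exp(self.log_survival(t))

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        lt = self.scale * t
        return (self.scale * self.shape * lt ** (self.shape - 1.0)) / (1.0 + lt**self.shape)

    def log_pdf(self, t):
        # f = h * S
        t = np.asarray(t, dtype=float)
        return np.log(self.hazard(t)) + self.log_survival(t)


@dataclass(frozen=True)
class ExponentialParams:
    """Constant-hazard comparator used only in the AIC ranking."""

    rate: float  # 1/months

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("exponential rate must be positive")

    n_params = 1

    def log_survival(self, t):
        return -self.rate * np.asarray(t, dtype=float)

    def survival(self, t):
        return np.exp(self.log_survival(t))

    def hazard(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.rate)

    def log_pdf(self, t):
        return math.log(self.rate) + self.log_survival(t)


@dataclass(frozen=True)
class WeibullParams:
    """Weibull comparator, S(t) = exp(-(scale*t)**shape)."""

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not (self.scale > 0 and self.shape > 0):
            raise ValueError("Weibull scale and shape must be positive")

    n_params = 2

    def log_survival(self, t):
        return -((self.scale * np.asarray(t, dtype=float)) ** self.shape)

    def survival(self, t):
        return np.exp(self.log_survival(t))

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        return self.scale * self.shape * (self.scale * t) ** (self.shape - 1.0)

    def log_pdf(self, t):
        return np.log(self.hazard(t)) + self.log_survival(t)


@dataclass(frozen=True)
class TreatmentEffect:
    """Hazard ratios (intervention vs reference) for OS and PFS with CIs."""

    os_hr: float
    pfs_hr: float
    os_hr_ci: tuple[float, float] | None = None
    pfs_hr_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name, hr, ci in (
            ("os", self.os_hr, self.os_hr_ci),
            ("pfs", self.pfs_hr, self.pfs_hr_ci),
        ):
            if hr <= 0:
                raise ValueError(f"{name} hazard ratio must be positive")
            if ci is not None:
                lo, hi = ci
                if not (0 < lo <= hr <= hi):
                    raise ValueError(f"{name} CI must satisfy 0 < low <= point <= high")


@dataclass(frozen=True)
class SurvivalCurve:
    """A baseline parametric curve with an optional treatment-effect multiplier.

    ``hr_mode='ph'`` applies the effect as proportional hazards,
    S_new = S_base**hr; ``'aft'`` as a time ratio, S_new(t) = S_base(hr*t).
    ``hr=1`` is the reference arm under either mode.
    """

    baseline: LogLogisticParams | ExponentialParams | WeibullParams
    hr: float = 1.0
    hr_mode: HRMode = "ph"

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")
        if self.hr_mode not in ("ph", "aft"):
            raise ValueError(f"unknown hr_mode {self.hr_mode!r}")

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival time must be nonnegative")
        if self.hr_mode == "ph":
            return np.exp(self.hr * self.baseline.log_survival(t))
        return self.baseline.survival(self.hr * t)

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("hazard is defined for t > 0")
        if self.hr_mode == "ph":
            return self.hr * self.baseline.hazard(t)
        return self.hr * self.baseline.hazard(self.hr * t)


def loglogistic_survival(params: LogLogisticParams, t) -> np.ndarray | float:
    """S(t) = 1/(1 + (lambda*t)**gamma); raises on negative t."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival time must be nonnegative")
    out = params.survival(t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def loglogistic_hazard(params: LogLogisticParams, t) -> np.ndarray | float:
    """Closed-form hazard -d/dt log S(t); defined for t > 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("hazard is defined for t > 0")
    out = params.hazard(t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def apply_hazard_ratio(curve: SurvivalCurve, hr: float) -> SurvivalCurve:
    """Compose a further hazard ratio onto a curve (multiplicative)."""
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return replace(curve, hr=curve.hr * hr)


def interval_event_prob(curve: SurvivalCurve, t_start: float, t_end: float) -> float:
    """Conditional probability of the event in (t_start, t_end].

    Returns 1 - S(t_end)/S(t_start), the per-cycle transition probability a
    state-transition model reads off a survival curve.
    """
    if not (0 <= t_start < t_end):
        raise ValueError("require 0 <= t_start < t_end")
    s0 = float(curve.survival(t_start))
    if s0 <= 0.0:
        raise ValueError("survival at interval start is zero; probability undefined")
    s1 = float(curve.survival(t_end))
    return min(1.0, max(0.0, 1.0 - s1 / s0))


def _censored_nll(params_factory, log_theta, times, events):
    try:
        dist = params_factory(*np.exp(log_theta))
    except ValueError:
        return np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(events == 1, dist.log_pdf(times), dist.log_survival(times))
    if not np.all(np.isfinite(ll)):
        return np.inf
    return -float(np.sum(ll))


def _fit_mle(params_factory, starts: Sequence[Sequence[float]], times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have the same length")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    if int(events.sum()) < 2:
        raise ValueError("need at least 2 events to fit a parametric model")
    # zero times contribute log f(0) = -inf for these families; nudge them
    times = np.where(times <= 0, 1e-8, times)

    best = None
    for x0 in starts:
        res = optimize.minimize(
            lambda lt: _censored_nll(params_factory, lt, times, events),
            x0=np.log(np.asarray(x0, dtype=float)),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = params_factory(*np.exp(best.x))
    return params, -float(best.fun)


# Fixed deterministic multistarts: fits involve no randomness.
_LL_STARTS = ((0.05, 1.0), (0.2, 2.0), (0.01, 0.8))


def fit_loglogistic_mle(times, events) -> tuple[LogLogisticParams, float]:
    """Censored MLE of the log-logistic (scale, shape); returns (params, logL)."""
    return _fit_mle(LogLogisticParams, _LL_STARTS, times, events)


def fit_exponential_mle(times, events) -> tuple[ExponentialParams, float]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if int(events.sum()) < 1:
        raise ValueError("need at least 1 event")
    # closed form: rate = events / total exposure
    rate = events.sum() / times.sum()
    dist = ExponentialParams(rate)
    ll = float(
        np.sum(np.where(events == 1, dist.log_pdf(times), dist.log_survival(times)))
    )
    return dist, ll


def fit_weibull_mle(times, events) -> tuple[WeibullParams, float]:
    return _fit_mle(WeibullParams, _LL_STARTS, times, events)


def select_model_aic(
    fits: Iterable[tuple[str, int, float]],
) -> list[tuple[str, int, float, float]]:
    """Rank candidate fits by AIC = 2k - 2 logL, ascending.

    Ties are broken by fewer parameters, then by name.  Returns rows of
    (name, k, logL, AIC).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    rows = [(name, k, ll, 2.0 * k - 2.0 * ll) for name, k, ll in fits]
    rows.sort(key=lambda r: (r[3], r[1], r[0]))
    return rows
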