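"""Survival statistics for model validation.

Kaplan–Meier curves, the k-group log-rank test, univariable Cox
proportional-hazards fits (Efron tie handling), and Holm–Bonferroni
step-down multiplicity control.  lifelines and statsmodels do the heavy
lifting; the surface here works directly on cohort arrays and returns
small result records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, UndefinedResultError

__all__ = [
    "SurvivalCurve",
    "EffectEstimate",
    "TestResult",
    "kaplan_meier",
    "logrank_test",
    "pairwise_logrank",
    "cox_univariable",
    "holm_bonferroni",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """A Kaplan–Meier product-limit estimate."""

    time: np.ndarray          # event-time grid (0 included)
    survival: np.ndarray      # S(t) on the grid, starts at 1, non-increasing
    at_risk: np.ndarray       # risk-set size just before each grid time
    censor_times: np.ndarray  # observed censoring times (plot ticks)

    def at(self, t: float) -> float:
        """S(t) by right-continuous step interpolation."""
        idx = np.searchsorted(self.time, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "survival": self.survival,
                             "at_risk": self.at_risk})


@dataclass(frozen=True)
class EffectEstimate:
    """A hazard ratio with its Wald 95% CI and p-value."""

    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    log_hr: float
    se_log_hr: float
    reference: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.hazard_ratio <= self.ci_upper):
            raise DomainError("effect CI must bracket the hazard ratio")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float | None
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError("p-value outside [0, 1]")


def _as_arrays(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if np.any(t < 0):
        raise DomainError("negative survival times")
    if len(t) != len(e):
        raise DomainError("times and events must have equal length")
    return t, e


def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit estimate of the survival function."""
    t, e = _as_arrays(times, events)
    if len(t) == 0:
        raise DomainError("empty sample")
    kmf = KaplanMeierFitter().fit(t, e)
    table = kmf.event_table
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    return SurvivalCurve(time=grid, survival=surv,
                         at_risk=table["at_risk"].to_numpy(dtype=float),
                         censor_times=np.sort(t[e == 0]))


def logrank_test(times, events, groups) -> TestResult:
    """k-group log-rank test (chi-square, k-1 df, hypergeometric variance)."""
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise DomainError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(t, g, e)
    k = len(labels)
    return TestResult(statistic=float(res.test_statistic), p_value=float(res.p_value),
                      df=float(k - 1), method="logrank")


def pairwise_logrank(times, events, groups) -> dict[tuple, TestResult]:
    """All pairwise two-group log-rank tests (feed the p-values to
    :func:`holm_bonferroni`)."""
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    labels = sorted(pd.unique(g).tolist())
    out: dict[tuple, TestResult] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            mask = (g == a) | (g == b)
            out[(a, b)] = logrank_test(t[mask], e[mask], g[mask])
    return out


def cox_univariable(times, events, x, reference: str = "") -> EffectEstimate:
    """Univariable Cox PH fit by partial-likelihood Newton iteration with
    Efron's tie correction.  ``x`` is a single numeric covariate or 0/1
    group indicator; returns HR = exp(beta) with Wald 95% CI and p."""
    t, e = _as_arrays(times, events)
    xv = np.asarray(x, dtype=float)
    if np.ptp(xv) == 0:
        raise DomainError("covariate is constant; hazard ratio undefined")
    if e.sum() == 0:
        raise UndefinedResultError("no events; Cox model cannot be fit")
    df = pd.DataFrame({"time": t, "event": e, "x": xv})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError, singular matrix, ...
        raise UndefinedResultError(f"Cox fit did not converge: {exc}") from exc
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    ci = cph.confidence_intervals_.loc["x"]
    return EffectEstimate(hazard_ratio=float(np.exp(beta)),
                          ci_lower=float(np.exp(ci.iloc[0])),
                          ci_upper=float(np.exp(ci.iloc[1])),
                          p_value=float(cph.summary.loc["x", "p"]),
                          log_hr=beta, se_log_hr=se, reference=reference)


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm's step-down procedure.

    Returns ``(reject, adjusted_p)`` aligned with the input order; a
    hypothesis is rejected iff its adjusted p-value is <= alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise DomainError("p_values must be a non-empty 1-d vector")
    if np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, adjusted
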