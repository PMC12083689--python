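"""Financial-toxicity association analyses.

Two tools: the Jonckheere–Terpstra test for a monotone trend of SIRI
across the ordered FT levels (0-3), and a multiple linear regression of
log2(SIRI) on the dichotomized FT group plus confounders.

The Jonckheere statistic is

    J = sum over ordered group pairs i < j of
        #{(u in group i, v in group j) : x_u < x_v} + 1/2 #ties,

large J indicating an increasing trend.  p-values come from a
tie-corrected normal approximation by default; an exact null distribution
(convolution of Mann–Whitney count distributions — the statistics of each
group against the pool of earlier groups are independent under H0) is
available for small untied samples, and a permutation fallback covers
everything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import norm

from .errors import DomainError
from .stats import TestResult

__all__ = ["jonckheere_test", "ols_regression", "RegressionFit"]


def _jt_statistic(values: np.ndarray, group_ids: np.ndarray, n_groups: int) -> float:
    j = 0.0
    for gi in range(n_groups - 1):
        xi = values[group_ids == gi]
        for gj in range(gi + 1, n_groups):
            xj = values[group_ids == gj]
            j += np.sum(xi[:, None] < xj[None, :]) + 0.5 * np.sum(xi[:, None] == xj[None, :])
    return float(j)


def _jt_null_moments(values: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    """Mean and tie-corrected variance of J under H0 (random labelling)."""
    n = sizes.sum()
    mean = (n * n - np.sum(sizes**2)) / 4.0
    _, tie_counts = np.unique(values, return_counts=True)
    t = tie_counts.astype(float)
    ni = sizes.astype(float)
    term1 = (n * (n - 1) * (2 * n + 5)
             - np.sum(ni * (ni - 1) * (2 * ni + 5))
             - np.sum(t * (t - 1) * (2 * t + 5))) / 72.0
    term2 = (np.sum(ni * (ni - 1) * (ni - 2)) * np.sum(t * (t - 1) * (t - 2))
             / (36.0 * n * (n - 1) * (n - 2)))
    term3 = (np.sum(ni * (ni - 1)) * np.sum(t * (t - 1))
             / (8.0 * n * (n - 1)))
    return float(mean), float(term1 + term2 + term3)


def _mwu_null_pmf(m: int, n: int) -> np.ndarray:
    """Exact null pmf of the Mann–Whitney U statistic for sizes (m, n),
    by the classical count recurrence
    N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1)."""
    row = [np.array([1.0]) for _ in range(n + 1)]      # i = 0
    for i in range(1, m + 1):
        new_row = [np.array([1.0])]                    # j = 0
        for j in range(1, n + 1):
            a = row[j]          # N(.; i-1, j), shifted by j
            b = new_row[j - 1]  # N(.; i, j-1)
            c = np.zeros(i * j + 1)
            c[j:j + len(a)] += a
            c[:len(b)] += b
            new_row.append(c)
        row = new_row
    counts = row[n]
    return counts / counts.sum()


def _jt_exact_pmf(sizes: np.ndarray) -> np.ndarray:
    """Exact null pmf of J for untied data.

    Under H0 the Mann–Whitney statistics of each group against the pool of
    the preceding groups are mutually independent, so the pmf of J is the
    convolution of their null pmfs.
    """
    pmf = np.array([1.0])
    pooled = int(sizes[0])
    for nj in sizes[1:]:
        nj = int(nj)
        if pooled * nj > 250_000:
            raise DomainError("sample too large for the exact Jonckheere p")
        pmf = np.convolve(pmf, _mwu_null_pmf(pooled, nj))
        pooled += nj
    return pmf


def jonckheere_test(values, groups, alternative: str = "increasing",
                    method: str = "normal", n_perm: int = 10000,
                    seed: int = 0) -> TestResult:
    """Jonckheere–Terpstra test for a monotone trend across ordered groups.

    ``groups`` may be any orderable labels; their sorted order defines the
    trend direction.  ``alternative`` is ``"increasing"``, ``"decreasing"``
    or ``"two-sided"``; ``method`` is ``"normal"`` (tie-corrected
    approximation), ``"exact"`` (untied data only) or ``"permutation"``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise DomainError("Jonckheere test needs at least 2 ordered groups")
    group_ids = np.searchsorted(labels, groups)
    sizes = np.bincount(group_ids, minlength=len(labels))
    if np.any(sizes == 0):
        raise DomainError("every ordered group must be non-empty")
    j_obs = _jt_statistic(values, group_ids, len(labels))
    mean, var = _jt_null_moments(values, sizes)

    if method == "normal":
        if var <= 0:
            raise DomainError("degenerate data: null variance of J is 0")
        z = (j_obs - mean) / np.sqrt(var)
        if alternative == "increasing":
            p = float(norm.sf(z))
        elif alternative == "decreasing":
            p = float(norm.cdf(z))
        elif alternative == "two-sided":
            p = float(min(1.0, 2.0 * norm.sf(abs(z))))
        else:
            raise DomainError(f"unknown alternative {alternative!r}")
        return TestResult(statistic=j_obs, p_value=p, df=None, method="jonckheere-normal")

    if method == "exact":
        if len(np.unique(values)) != len(values):
            raise DomainError("exact Jonckheere p requires untied values")
        pmf = _jt_exact_pmf(sizes)
        support = np.arange(len(pmf), dtype=float)
        ge = float(pmf[support >= j_obs - 1e-9].sum())
        le = float(pmf[support <= j_obs + 1e-9].sum())
        if alternative == "increasing":
            p = ge
        elif alternative == "decreasing":
            p = le
        elif alternative == "two-sided":
            p = min(1.0, 2.0 * min(ge, le))
        else:
            raise DomainError(f"unknown alternative {alternative!r}")
        return TestResult(statistic=j_obs, p_value=p, df=None, method="jonckheere-exact")

    if method == "permutation":
        rng = np.random.default_rng(seed)
        count_ge = 0
        count_le = 0
        vals = values.copy()
        for _ in range(n_perm):
            rng.shuffle(vals)
            j_perm = _jt_statistic(vals, group_ids, len(labels))
            count_ge += j_perm >= j_obs - 1e-9
            count_le += j_perm <= j_obs + 1e-9
        ge = (count_ge + 1) / (n_perm + 1)
        le = (count_le + 1) / (n_perm + 1)
        if alternative == "increasing":
            p = ge
        elif alternative == "decreasing":
            p = le
        elif alternative == "two-sided":
            p = min(1.0, 2.0 * min(ge, le))
        else:
            raise DomainError(f"unknown alternative {alternative!r}")
        return TestResult(statistic=j_obs, p_value=float(p), df=None,
                          method="jonckheere-permutation")

    raise DomainError(f"unknown method {method!r}")


@dataclass
class RegressionFit:
    """A fitted OLS model of log2(SIRI) on FT group plus confounders."""

    table: pd.DataFrame        # term, beta, ci_lower, ci_upper, p_value
    residual_variance: float
    n: int
    r_squared: float

    def coefficient(self, term_substring: str) -> pd.Series:
        hit = self.table[self.table["term"].str.contains(term_substring, regex=False)]
        if len(hit) != 1:
            raise DomainError(f"term {term_substring!r} matches {len(hit)} rows")
        return hit.iloc[0]


def ols_regression(data: pd.DataFrame, response: str,
                   continuous: list[str] = (),
                   categorical: dict[str, str] | None = None) -> RegressionFit:
    """OLS of ``response`` on continuous terms plus treatment-coded
    categorical terms.

    ``categorical`` maps column name -> reference level.  Returns classical
    (homoskedastic) standard errors, t-based 95% CIs and two-sided p-values.
    """
    categorical = categorical or {}
    terms = list(continuous) + [
        f"C({col}, Treatment(reference={ref!r}))" for col, ref in categorical.items()
    ]
    if not terms:
        raise DomainError("no regressors supplied")
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise DomainError("rank-deficient design matrix (collinear terms)")
    res = model.fit()
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame({
        "term": res.params.index,
        "beta": res.params.to_numpy(),
        "ci_lower": ci[0].to_numpy(),
        "ci_upper": ci[1].to_numpy(),
        "p_value": res.pvalues.to_numpy(),
    })
    return RegressionFit(table=table, residual_variance=float(res.mse_resid),
                         n=int(res.nobs), r_squared=float(res.rsquared))
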