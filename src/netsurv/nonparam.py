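"""Non-parametric net-survival estimators.

Three estimators with different data requirements:

* cause-specific Kaplan-Meier (``km_net``): needs a cause-of-death
  indicator; other-cause deaths and live subjects are right-censored;
* weighted Nelson-Aalen (``weighted_nelson_aalen``): cause-specific events,
  with counting and at-risk processes inverse-weighted by each subject's
  expected survival ``S_{P,i}`` from a population life table (the inverse
  probability of censoring weighting that removes the informative censoring
  induced by demographics);
* Pohar-Perme (``pohar_perme``): population-based; needs only vital status
  plus the life table.  The cumulative excess hazard is the weighted
  all-cause Nelson-Aalen term minus the integrated weighted population
  hazard of the at-risk set.

All estimators are step functions evaluated at event times; deaths precede
censorings at tied times.  Weighted curves may locally exceed 1 and are
reported uncapped (``SurvivalCurve.capped()`` post-caps on request).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .curves import SurvivalCurve
from .lifetable import RateTable

__all__ = [
    "km_net",
    "weighted_nelson_aalen",
    "pohar_perme",
    "KaplanMeierNet",
    "WeightedNelsonAalen",
    "PoharPerme",
]

Z95 = 1.959963984540054


def _check_cause(data: pd.DataFrame):
    if "cause" not in data.columns or data["cause"].isna().all():
        raise ValueError(
            "cause-of-death indicator absent: use a population-based "
            "estimator (Pohar-Perme or the RBS model) instead")
    cause = np.asarray(data["cause"], dtype=float)
    status = np.asarray(data["status"], dtype=float)
    if np.any((cause == 1) & (status == 0)):
        raise ValueError("cause = 1 requires status = 1")
    return cause


def km_net(data: pd.DataFrame) -> SurvivalCurve:
    """Cause-specific Kaplan-Meier estimate of net survival.

    Product-limit over cancer-death times with Greenwood variance and a
    log-survival-transformed 95% CI.
    """
    cause = _check_cause(data)
    time = np.asarray(data["time"], dtype=float)
    event = cause == 1
    grid = np.unique(time[event])
    if grid.size == 0:
        return SurvivalCurve(times=np.asarray([]), estimate=np.asarray([]),
                             variance=np.asarray([]), ci_low=np.asarray([]),
                             ci_high=np.asarray([]), estimator="km",
                             at_risk=np.asarray([]))
    at_risk = (time[:, None] >= grid[None, :]).sum(axis=0).astype(float)
    deaths = ((time[:, None] == grid[None, :]) & event[:, None]).sum(axis=0).astype(float)
    frac = 1.0 - deaths / at_risk
    surv = np.cumprod(frac)
    # Greenwood on log S; CI via S * exp(+-z * se(log S))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(deaths / (at_risk * (at_risk - deaths)))
    var = surv ** 2 * gw
    se_log = np.sqrt(gw)
    lo = surv * np.exp(-Z95 * se_log)
    hi = np.minimum(surv * np.exp(Z95 * se_log), 1.0)
    zero = surv == 0
    lo[zero] = 0.0
    hi[zero] = 0.0
    return SurvivalCurve(times=grid, estimate=surv, variance=var,
                         ci_low=lo, ci_high=hi, estimator="km", at_risk=at_risk)


def _expected_cumhaz_matrix(rt: RateTable, data: pd.DataFrame, grid: np.ndarray):
    """Lambda_{P,i}(min(u_j, t_i)) for all subjects i and grid times u_j."""
    time = np.asarray(data["time"], dtype=float)
    age = np.asarray(data["age_dx"], dtype=float)
    year = np.asarray(data["year_dx"], dtype=float)
    sex = np.asarray(data["sex"])
    edges, cum = rt.cumulative_hazard_edges(age, year, sex, time)
    n = time.size
    out = np.empty((n, grid.size))
    for i in range(n):
        out[i] = np.interp(np.minimum(grid, time[i]), edges[i], cum[i])
    return out


def weighted_nelson_aalen(data: pd.DataFrame, rt: RateTable) -> SurvivalCurve:
    """Inverse-expected-survival-weighted Nelson-Aalen net survival.

    ``S = exp(-sum_j dN_E^w(u_j) / Y^w(u_j))`` over cancer-death times,
    with ``dN^w = dN / S_{P,i}`` and ``Y^w = Y / S_{P,i}``; the expected
    survival is continuous, so its left limit equals its value.
    """
    cause = _check_cause(data)
    time = np.asarray(data["time"], dtype=float)
    event = cause == 1
    grid = np.unique(time[event])
    if grid.size == 0:
        return SurvivalCurve(times=np.asarray([]), estimate=np.asarray([]),
                             variance=np.asarray([]), ci_low=np.asarray([]),
                             ci_high=np.asarray([]), estimator="wna",
                             at_risk=np.asarray([]))
    W = np.exp(_expected_cumhaz_matrix(rt, data, grid))   # 1 / S_{P,i}(u_j)
    at = time[:, None] >= grid[None, :]
    dies = (time[:, None] == grid[None, :]) & event[:, None]
    Yw = np.sum(W, axis=0, where=at)
    dNw = np.sum(W, axis=0, where=dies)
    inc = dNw / Yw
    cumhaz = np.cumsum(inc)
    surv = np.exp(-cumhaz)
    var_log = np.cumsum(dNw / Yw ** 2)
    lo = np.exp(-(cumhaz + Z95 * np.sqrt(var_log)))
    hi = np.exp(-(cumhaz - Z95 * np.sqrt(var_log)))
    var = surv ** 2 * var_log
    return SurvivalCurve(times=grid, estimate=surv, variance=var,
                         ci_low=lo, ci_high=np.minimum(hi, 1.0),
                         estimator="wna", at_risk=Yw)


def pohar_perme(data: pd.DataFrame, rt: RateTable) -> SurvivalCurve:
    """Pohar-Perme estimator of net survival (population-based).

    Cumulative excess hazard at all-cause death times:
    ``int dN^w / Y^w  -  int sum_i Y_i^w lambda_{P,i} du / Y^w``.
    The numerator of the background term is integrated exactly over each
    inter-event interval via ``d/du exp(Lambda_{P,i}(u)) = Y_i^w lambda_{P,i}``;
    the denominator ``Y^w`` is evaluated at the right endpoint (the event
    time), the same convention as the first term.  Pointwise variance is the
    counting-process estimator ``sum dN_i / S_{P,i}^2 / (Y^w)^2``.
    """
    time = np.asarray(data["time"], dtype=float)
    status = np.asarray(data["status"], dtype=float)
    grid = np.unique(time[status == 1])
    if grid.size == 0:
        return SurvivalCurve(times=np.asarray([]), estimate=np.asarray([]),
                             variance=np.asarray([]), ci_low=np.asarray([]),
                             ci_high=np.asarray([]), estimator="pp",
                             at_risk=np.asarray([]))
    L = _expected_cumhaz_matrix(rt, data, grid)           # clamped at t_i
    W = np.exp(L)
    at = time[:, None] >= grid[None, :]
    dies = (time[:, None] == grid[None, :]) & (status[:, None] == 1)
    Yw = np.sum(W, axis=0, where=at)
    dNw = np.sum(W, axis=0, where=dies)
    # exact integral of sum_i Y_i^w lambda_{P,i} over (u_{j-1}, u_j]:
    # subjects leaving mid-interval contribute up to their exit because L is
    # clamped at t_i.
    E_prev = np.concatenate([np.ones((time.size, 1)), W[:, :-1]], axis=1)
    bg_num = np.sum(W - E_prev, axis=0)
    term1 = np.cumsum(dNw / Yw)
    term2 = np.cumsum(bg_num / Yw)
    cumhaz = term1 - term2
    surv = np.exp(-cumhaz)
    var_log = np.cumsum(np.sum(W ** 2, axis=0, where=dies) / Yw ** 2)
    lo = np.exp(-(cumhaz + Z95 * np.sqrt(var_log)))
    hi = np.exp(-(cumhaz - Z95 * np.sqrt(var_log)))
    var = surv ** 2 * var_log
    return SurvivalCurve(times=grid, estimate=surv, variance=var,
                         ci_low=lo, ci_high=hi, estimator="pp", at_risk=Yw)


# -- sklearn-style wrappers ---------------------------------------------------

class _CurveEstimator(BaseEstimator):
    """Shared fit/attribute plumbing for the curve estimators."""

    def fit(self, X: pd.DataFrame, y=None):
        curve = self._estimate(X)
        self.curve_ = curve
        self.times_ = curve.times
        self.survival_ = curve.estimate
        self.variance_ = curve.variance
        self.ci_low_ = curve.ci_low
        self.ci_high_ = curve.ci_high
        return self

    def predict_net_survival(self, times):
        return self.curve_.at(times)


class KaplanMeierNet(_CurveEstimator):
    """Cause-specific Kaplan-Meier estimator of net survival."""

    def __init__(self, cap=False):
        self.cap = cap

    def _estimate(self, X):
        c = km_net(X)
        return c.capped() if self.cap else c


class WeightedNelsonAalen(_CurveEstimator):
    """Weighted Nelson-Aalen estimator (cause-specific, life-table weights)."""

    def __init__(self, rate_table=None, cap=False):
        self.rate_table = rate_table
        self.cap = cap

    def _estimate(self, X):
        c = weighted_nelson_aalen(X, self.rate_table)
        return c.capped() if self.cap else c


class PoharPerme(_CurveEstimator):
    """Pohar-Perme estimator of net survival (population-based)."""

    def __init__(self, rate_table=None, cap=False):
        self.rate_table = rate_table
        self.cap = cap

    def _estimate(self, X):
        c = pohar_perme(X, self.rate_table)
        return c.capped() if self.cap else c
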