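"""Cause-specific Cox model for the excess hazard.

The excess hazard is ``lambda_E(t, x) = lambda_{E,0}(t) exp(beta' x)`` with
cancer deaths as events and everything else right-censored.  ``beta`` is the
Breslow-ties partial-likelihood maximizer (Newton-Raphson with step
halving); the baseline cumulative excess hazard is the Breslow estimator

    Lambda_{E,0}(t) = sum_{t_j <= t} d_j / sum_{i in R(t_j)} exp(beta' x_i)

and the population-averaged net survival is

    S(t) = (1/n) sum_i exp(-Lambda_{E,0}(t) exp(beta' x_i)).

Confidence intervals for the averaged net survival (needed for coverage
studies) come from a nonparametric bootstrap over subjects, since no
closed-form variance exists for the average of correlated individual
survivals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .curves import SurvivalCurve
from .nonparam import _check_cause

__all__ = ["CoxFit", "fit_cox_excess", "breslow_cumhaz", "cox_net_survival",
           "cox_net_curve", "CoxExcessHazard"]

Z95 = 1.959963984540054


@dataclass
class CoxFit:
    """Fitted cause-specific Cox excess-hazard model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    names: tuple
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    loglik: float
    n_iter: int
    dropped: tuple = ()

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_beta))
        return pd.DataFrame({
            "name": list(self.names),
            "coef": self.beta,
            "EHR": np.exp(self.beta),
            "EHR_lo95": np.exp(self.beta - Z95 * se),
            "EHR_hi95": np.exp(self.beta + Z95 * se),
        })

    def cumhaz_at(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        out = np.where(idx >= 0, self.baseline_cumhaz[np.clip(idx, 0, None)], 0.0)
        return float(out) if out.ndim == 0 else out


def _partial_loglik(beta, time, event, X):
    """Breslow-ties partial log-likelihood, gradient and Hessian."""
    order = np.argsort(-time, kind="stable")   # descending time
    t_s, e_s, X_s = time[order], event[order], X[order]
    eta = X_s @ beta
    w = np.exp(eta)
    cum_w = np.cumsum(w)                       # sum over risk set (t_i >= t)
    cum_wx = np.cumsum(w[:, None] * X_s, axis=0)
    cum_wxx = np.cumsum(w[:, None, None] * (X_s[:, :, None] * X_s[:, None, :]), axis=0)
    # risk set at an event time is a prefix of the descending order; ties
    # share the risk set, so index by the last occurrence of each time
    last_occ = {}
    for pos, tv in enumerate(t_s):
        last_occ[tv] = pos
    ll, g, H = 0.0, np.zeros(beta.size), np.zeros((beta.size, beta.size))
    ev_pos = np.nonzero(e_s)[0]
    for pos in ev_pos:
        r = last_occ[t_s[pos]]
        s0 = cum_w[r]
        s1 = cum_wx[r]
        s2 = cum_wxx[r]
        ll += eta[pos] - np.log(s0)
        m = s1 / s0
        g += X_s[pos] - m
        H -= s2 / s0 - np.outer(m, m)
    return ll, g, H


def fit_cox_excess(data: pd.DataFrame, covariates, gtol: float = 1e-8,
                   max_iter: int = 50) -> CoxFit:
    """Fit the cause-specific Cox excess-hazard model.

    Constant covariates are dropped with a warning (their effect is
    unidentifiable); apparent separation (|beta| running away) triggers a
    warning.
    """
    cause = _check_cause(data)
    time = np.asarray(data["time"], dtype=float)
    event = cause == 1
    if event.sum() < 1:
        raise ValueError("at least one cancer death is required")
    names = list(covariates)
    X = np.asarray(data[names], dtype=float)
    keep = X.std(axis=0) > 0
    dropped = tuple(n for n, k in zip(names, keep) if not k)
    if dropped:
        warnings.warn(f"dropping constant covariate(s): {dropped}", UserWarning)
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    if X.shape[1] == 0:
        beta = np.empty(0)
        cov = np.empty((0, 0))
        ll = _partial_loglik(beta, time, event, X)[0]
        n_iter = 0
    else:
        beta = np.zeros(X.shape[1])
        ll, g, H = _partial_loglik(beta, time, event, X)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            step = np.linalg.solve(-H, g)
            # step halving on the partial likelihood
            lam = 1.0
            for _ in range(30):
                ll_new, g_new, H_new = _partial_loglik(beta + lam * step, time, event, X)
                if ll_new >= ll - 1e-12:
                    break
                lam *= 0.5
            beta = beta + lam * step
            ll, g, H = ll_new, g_new, H_new
            if np.linalg.norm(g) < gtol:
                break
        else:
            raise RuntimeError(
                f"Cox fit did not converge in {max_iter} iterations; "
                f"|grad| = {np.linalg.norm(g):.3g}, beta = {beta}")
        if np.linalg.norm(g) >= gtol:
            raise RuntimeError(
                f"Cox fit did not converge; |grad| = {np.linalg.norm(g):.3g}")
        if np.any(np.abs(beta) > 20):
            warnings.warn("possible separation: |beta| > 20", UserWarning)
        cov = np.linalg.inv(-H)
    bt, bc = _breslow(beta, time, event, X)
    return CoxFit(beta=beta, cov_beta=cov, names=tuple(names),
                  baseline_times=bt, baseline_cumhaz=bc, loglik=float(ll),
                  n_iter=n_iter, dropped=dropped)


def _breslow(beta, time, event, X):
    grid = np.unique(time[event])
    risk = np.exp(X @ beta) if X.shape[1] else np.ones(time.size)
    denom = np.array([risk[time >= u].sum() for u in grid])
    deaths = np.array([(event & (time == u)).sum() for u in grid], dtype=float)
    return grid, np.cumsum(deaths / denom)


def breslow_cumhaz(fit: CoxFit, data: pd.DataFrame, beta=None):
    """Recompute the Breslow baseline cumulative excess hazard on ``data``.

    With ``beta = 0`` this is the Nelson-Aalen cumulative hazard of cancer
    deaths (the unadjusted cumulative excess hazard).
    """
    cause = _check_cause(data)
    time = np.asarray(data["time"], dtype=float)
    event = cause == 1
    b = fit.beta if beta is None else np.asarray(beta, dtype=float)
    X = (np.asarray(data[list(fit.names)], dtype=float)
         if fit.names else np.empty((time.size, 0)))
    grid, cum = _breslow(b, time, event, X)
    return grid, cum


def cox_net_survival(fit: CoxFit, data: pd.DataFrame, t):
    """Population-averaged net survival ``(1/n) sum_i exp(-Lambda_0(t) e^{eta_i})``."""
    X = (np.asarray(data[list(fit.names)], dtype=float)
         if fit.names else np.empty((len(data), 0)))
    risk = np.exp(X @ fit.beta) if X.shape[1] else np.ones(len(data))
    lam = np.atleast_1d(fit.cumhaz_at(t))
    S = np.exp(-np.outer(risk, lam)).mean(axis=0)
    return float(S[0]) if np.isscalar(t) else S


def cox_net_curve(fit: CoxFit, data: pd.DataFrame, times=None,
                  bootstrap: int = 0, fit_data: pd.DataFrame | None = None,
                  seed=None) -> SurvivalCurve:
    """Net-survival curve for the subjects in ``data``.

    With ``bootstrap > 0``, percentile CIs are computed by refitting on
    bootstrap resamples of ``fit_data`` (defaults to ``data``) and averaging
    over the original ``data`` covariates.
    """
    times = (fit.baseline_times if times is None
             else np.atleast_1d(np.asarray(times, dtype=float)))
    est = np.atleast_1d(cox_net_survival(fit, data, times))
    var = np.full(times.size, np.nan)
    lo = np.full(times.size, np.nan)
    hi = np.full(times.size, np.nan)
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        src = data if fit_data is None else fit_data
        reps = np.empty((bootstrap, times.size))
        n = len(src)
        for b in range(bootstrap):
            idx = rng.integers(0, n, n)
            boot = src.iloc[idx]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    f = fit_cox_excess(boot, list(fit.names) + list(fit.dropped))
                reps[b] = np.atleast_1d(cox_net_survival(f, data, times))
            except (RuntimeError, ValueError):
                reps[b] = np.nan
        var = np.nanvar(reps, axis=0, ddof=1)
        lo = np.nanquantile(reps, 0.025, axis=0)
        hi = np.nanquantile(reps, 0.975, axis=0)
    return SurvivalCurve(times=times, estimate=est, variance=var,
                         ci_low=lo, ci_high=hi, estimator="cox")


class CoxExcessHazard(BaseEstimator):
    """Cause-specific Cox excess-hazard model, sklearn-style."""

    def __init__(self, covariates=(), bootstrap=0, random_state=None):
        self.covariates = covariates
        self.bootstrap = bootstrap
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        fit = fit_cox_excess(X, list(self.covariates))
        self.result_ = fit
        self.coef_ = fit.beta
        self.cov_ = fit.cov_beta
        self.baseline_times_ = fit.baseline_times
        self.baseline_cumhaz_ = fit.baseline_cumhaz
        self.loglik_ = fit.loglik
        self._train = X
        return self

    def predict_net_survival(self, times, data: pd.DataFrame | None = None,
                             ci: bool = False) -> SurvivalCurve:
        data = self._train if data is None else data
        return cox_net_curve(self.result_, data, times,
                             bootstrap=self.bootstrap if ci else 0,
                             fit_data=self._train, seed=self.random_state)

    def summary(self) -> pd.DataFrame:
        return self.result_.summary()
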