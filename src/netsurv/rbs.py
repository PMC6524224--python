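"""Rescaled B-spline (RBS) excess-hazard model.

The observed (all-cause) hazard of subject ``i`` at follow-up time ``t`` is
modelled additively as

    lambda_O(t | x_i) = [sum_j nu_j B_{j,3}(t)] exp(beta' x_i)
                        + alpha * lambda_P(t | z_i)

where the baseline excess hazard is a quadratic B-spline (order 3, two
interior knots by default), ``beta`` are proportional covariate effects,
``lambda_P`` is the expected hazard matched from a population life table and
``alpha > 0`` is a selection scale: the factor by which trial participants'
other-cause mortality differs from the general population's.  With
``alpha = 1`` the model reduces to the classical additive excess-hazard
model with a B-spline baseline and proportional effects.

The log-likelihood uses only the all-cause death indicator ``delta`` (the
cause of death is never consulted), which makes the model insensitive to
cause-of-death misclassification:

    l = sum_i [ -exp(beta' x_i) * int_0^{t_i} sum_j nu_j B_{j,3}(u) du
                - alpha * Lambda_P(t_i | z_i)
                + delta_i * log(lambda_E(t_i | x_i) + alpha lambda_P(t_i)) ]

Maximisation is done with a box-constrained quasi-Newton method
(``nu_j >= 0``, ``alpha >= 1e-6``), with analytic gradients and a multistart
guard.  Net survival is ``exp(-Lambda_E)``; confidence bands come from
Monte-Carlo draws of the parameter vector from its asymptotic normal law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess

from .curves import SurvivalCurve
from .lifetable import RateTable

__all__ = [
    "SplineSpec",
    "RBSParams",
    "RBSFit",
    "bspline_basis",
    "integrated_bspline_basis",
    "excess_hazard",
    "cumulative_excess_hazard",
    "rbs_loglik",
    "fit_rbs",
    "rbs_net_survival",
    "mc_confidence",
    "RescaledBSpline",
]

ALPHA_FLOOR = 1e-6


@dataclass(frozen=True)
class SplineSpec:
    """Quadratic B-spline specification on [boundary[0], boundary[1]].

    ``order`` is the spline order (3 = quadratic, degree 2); with two
    interior knots the basis has ``2 + 3 = 5`` elements.
    """

    interior_knots: tuple = (1.0, 5.0)
    boundary: tuple = (0.0, 15.0)
    order: int = 3

    def __post_init__(self):
        lo, hi = self.boundary
        ks = tuple(float(k) for k in self.interior_knots)
        if any(not (lo < k < hi) for k in ks):
            raise ValueError(f"interior knots {ks} must lie strictly inside {self.boundary}")
        if any(k2 <= k1 for k1, k2 in zip(ks, ks[1:])):
            raise ValueError("interior knots must be strictly ascending")
        object.__setattr__(self, "interior_knots", ks)
        object.__setattr__(self, "boundary", (float(lo), float(hi)))

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def basis_count(self) -> int:
        return len(self.interior_knots) + self.order

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.r_[[lo] * self.order, self.interior_knots, [hi] * self.order]


@lru_cache(maxsize=32)
def _basis_elements(spec: SplineSpec):
    """Per-element BSpline objects and their antiderivatives."""
    kv = spec.knot_vector
    k = spec.degree
    elems, antis = [], []
    for j in range(spec.basis_count):
        c = np.zeros(spec.basis_count)
        c[j] = 1.0
        spl = BSpline(kv, c, k, extrapolate=False)
        elems.append(spl)
        antis.append(spl.antiderivative())
    return tuple(elems), tuple(antis)


def _check_domain(spec: SplineSpec, t: np.ndarray):
    lo, hi = spec.boundary
    if np.any(t < lo) or np.any(t > hi):
        raise ValueError(f"time outside spline boundary {spec.boundary}")


def bspline_basis(spec: SplineSpec, t):
    """Design matrix of the basis at times ``t`` (rows sum to 1)."""
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    _check_domain(spec, t)
    dm = BSpline.design_matrix(t, spec.knot_vector, spec.degree).toarray()
    return dm[0] if scalar else dm


def integrated_bspline_basis(spec: SplineSpec, t):
    """Matrix of exact integrals ``int_0^t B_j(u) du`` (piecewise cubic)."""
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    _check_domain(spec, t)
    _, antis = _basis_elements(spec)
    lo = spec.boundary[0]
    cols = [anti(t) - anti(lo) for anti in antis]
    out = np.column_stack(cols)
    return out[0] if scalar else out


@dataclass
class RBSParams:
    """Parameter vector: spline coefficients ``nu`` (>= 0), covariate
    effects ``beta`` and selection scale ``alpha`` (> 0)."""

    nu: np.ndarray
    beta: np.ndarray
    alpha: float

    def __post_init__(self):
        self.nu = np.asarray(self.nu, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any(self.nu < 0):
            raise ValueError("spline coefficients nu must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    def pack(self) -> np.ndarray:
        return np.r_[self.nu, self.beta, self.alpha]

    @staticmethod
    def unpack(theta: np.ndarray, k: int, p: int) -> "RBSParams":
        return RBSParams(nu=theta[:k], beta=theta[k:k + p], alpha=float(theta[k + p]))


def excess_hazard(params: RBSParams, spec: SplineSpec, t, x=None):
    """Excess hazard ``[sum_j nu_j B_j(t)] exp(beta' x)`` (per year)."""
    base = bspline_basis(spec, t) @ params.nu
    lin = 0.0 if x is None or params.beta.size == 0 else float(params.beta @ np.asarray(x, dtype=float))
    return base * np.exp(lin)


def cumulative_excess_hazard(params: RBSParams, spec: SplineSpec, t, x=None):
    """Exact cumulative excess hazard ``exp(beta' x) int_0^t sum nu_j B_j``."""
    base = integrated_bspline_basis(spec, t) @ params.nu
    lin = 0.0 if x is None or params.beta.size == 0 else float(params.beta @ np.asarray(x, dtype=float))
    return base * np.exp(lin)


# -- likelihood ---------------------------------------------------------------

@dataclass
class _ModelData:
    """Per-subject quantities precomputed once per (data, table, spec)."""

    time: np.ndarray
    delta: np.ndarray
    X: np.ndarray          # (n, p) covariate matrix
    B: np.ndarray          # basis at event/censoring times (n, k)
    I: np.ndarray          # integrated basis at those times (n, k)
    lam_p: np.ndarray      # population hazard at t_i, scale 1
    Lam_p: np.ndarray      # cumulative population hazard at t_i, scale 1
    names: tuple


def _prepare(data: pd.DataFrame, rt: RateTable | None, spec: SplineSpec,
             covariates) -> _ModelData:
    t = np.asarray(data["time"], dtype=float)
    delta = np.asarray(data["status"], dtype=float)
    names = tuple(covariates or ())
    X = (np.asarray(data[list(names)], dtype=float)
         if names else np.empty((t.size, 0)))
    B = bspline_basis(spec, t)
    I = integrated_bspline_basis(spec, t)
    if rt is None:
        lam_p = np.zeros_like(t)
        lam_P_cum = np.zeros_like(t)
    else:
        age = np.asarray(data["age_dx"], dtype=float)
        year = np.asarray(data["year_dx"], dtype=float)
        sex = np.asarray(data["sex"])
        sex_idx = rt.sex_index(sex)
        age_idx = rt._age_idx(age + t)
        year_idx = np.floor(year + t).astype(int) - rt.years[0]
        rt._check_range(age_idx, year_idx, context="at subject follow-up ends")
        lam_p = rt.rate[age_idx, year_idx, sex_idx]
        lam_P_cum = rt.cumulative_hazard(age, year, sex, t)
    return _ModelData(time=t, delta=delta, X=X, B=B, I=I,
                      lam_p=lam_p, Lam_p=np.atleast_1d(lam_P_cum), names=names)


def _loglik_and_grad(theta: np.ndarray, md: _ModelData, k: int, p: int):
    nu, beta, alpha = theta[:k], theta[k:k + p], theta[k + p]
    eta = md.X @ beta if p else np.zeros(md.time.size)
    risk = np.exp(eta)
    base = md.B @ nu
    ibase = md.I @ nu
    lam_e = base * risk
    total = lam_e + alpha * md.lam_p
    dead = md.delta > 0
    if np.any(total[dead] <= 0):
        return -np.inf, np.zeros_like(theta)
    ll = -np.sum(ibase * risk) - alpha * np.sum(md.Lam_p)
    ll += np.sum(np.log(total[dead]))
    inv_tot = np.zeros_like(total)
    inv_tot[dead] = 1.0 / total[dead]
    g_nu = -md.I.T @ risk + md.B.T @ (risk * inv_tot)
    g_beta = (md.X.T @ (-ibase * risk + lam_e * inv_tot)) if p else np.empty(0)
    g_alpha = -np.sum(md.Lam_p) + np.sum(md.lam_p * inv_tot)
    return ll, np.r_[g_nu, g_beta, g_alpha]


def rbs_loglik(params: RBSParams, data: pd.DataFrame, rt: RateTable | None,
               spec: SplineSpec, covariates=()) -> float:
    """Log-likelihood of the model at ``params`` on subject-level data.

    Uses only the all-cause status column; any death time at which the total
    hazard is zero yields ``-inf`` (optimizer-safe).
    """
    md = _prepare(data, rt, spec, covariates)
    k, p = params.nu.size, params.beta.size
    ll, _ = _loglik_and_grad(params.pack(), md, k, p)
    return float(ll)


@dataclass
class RBSFit:
    """Fitted RBS model."""

    params: RBSParams
    spec: SplineSpec
    cov: np.ndarray | None
    loglik: float
    names: tuple
    converged: bool
    n_iter: int
    grad_norm: float
    multistart_logliks: tuple = ()
    fixed_alpha: bool = False

    @property
    def theta(self) -> np.ndarray:
        return self.params.pack()

    def summary(self) -> pd.DataFrame:
        """Coefficient table with Wald 95% CIs (EHR rows on the log scale)."""
        k = self.params.nu.size
        rows = []
        se = (np.sqrt(np.diag(self.cov)) if self.cov is not None
              else np.full(self.theta.size, np.nan))
        for j, v in enumerate(self.params.nu):
            rows.append(("nu_%d" % j, v, np.nan, np.nan))
        for j, name in enumerate(self.names):
            b, s = self.params.beta[j], se[k + j]
            rows.append((name, b, b - 1.96 * s, b + 1.96 * s))
            rows.append((f"EHR({name})", np.exp(b),
                         np.exp(b - 1.96 * s), np.exp(b + 1.96 * s)))
        a, s = self.params.alpha, se[-1]
        if self.fixed_alpha:
            rows.append(("alpha", a, a, a))
        else:
            rows.append(("alpha", a, a - 1.96 * s, a + 1.96 * s))
        return pd.DataFrame(rows, columns=["name", "estimate", "lo95", "hi95"])


def _initial_points(md: _ModelData, k: int, p: int, alpha0: float,
                    perturbations=(1.0, 0.5, 2.0)):
    person_time = float(np.sum(md.time))
    crude = float(np.sum(md.delta)) / max(person_time, 1e-12)
    crude = max(crude, 1e-4)
    pts = []
    for f in perturbations:
        theta0 = np.r_[np.full(k, crude * f), np.zeros(p), alpha0 * f]
        pts.append(theta0)
    return pts


def _projected_grad_norm(theta, grad, bounds):
    pg = np.array(grad, dtype=float)
    for i, (lo, hi) in enumerate(bounds):
        if lo is not None and theta[i] <= lo + 1e-12 and grad[i] < 0:
            pg[i] = 0.0
        if hi is not None and theta[i] >= hi - 1e-12 and grad[i] > 0:
            pg[i] = 0.0
    return float(np.linalg.norm(pg))


def fit_rbs(
    data: pd.DataFrame,
    rt: RateTable | None,
    spec: SplineSpec | None = None,
    covariates=(),
    fix_alpha: float | None = None,
    init_alpha: float = 1.0,
    n_starts: int = 3,
    gtol: float = 1e-5,
    compute_cov: bool = True,
) -> RBSFit:
    """Maximum-likelihood fit of the RBS model.

    ``nu_j >= 0`` and ``alpha >= 1e-6`` are enforced as box constraints
    (L-BFGS-B); ``fix_alpha`` pins the selection scale (e.g. 1 recovers the
    classical B-spline excess-hazard model).  The fit is restarted from
    ``n_starts`` perturbed initial points and the best optimum kept; the
    covariance is the inverse of the numerically differentiated observed
    information.
    """
    if spec is None:
        spec = SplineSpec(boundary=(0.0, float(np.max(data["time"]))))
    md = _prepare(data, rt, spec, covariates)
    if md.delta.sum() < 1:
        raise ValueError("at least one all-cause death is required")
    k, p = spec.basis_count, md.X.shape[1]
    if fix_alpha is None and not np.any(md.lam_p > 0):
        warnings.warn(
            "population hazard is identically zero along all trajectories: "
            "the selection scale alpha is not identifiable; fix it with "
            "fix_alpha.", UserWarning)
    bounds = [(0.0, None)] * k + [(None, None)] * p
    if fix_alpha is not None:
        bounds += [(float(fix_alpha), float(fix_alpha))]
        init_alpha = float(fix_alpha)
    else:
        bounds += [(ALPHA_FLOOR, None)]

    def neg(theta):
        ll, g = _loglik_and_grad(theta, md, k, p)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(theta)
        return -ll, -g

    results = []
    perturb = (1.0, 0.5, 2.0, 0.25, 4.0)[:max(n_starts, 1)]
    for theta0 in _initial_points(md, k, p, init_alpha, perturb):
        if fix_alpha is not None:
            theta0[-1] = float(fix_alpha)
        res = minimize(neg, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 5000, "ftol": 1e-18, "gtol": 1e-14,
                                "maxls": 200})
        results.append(res)
    best = max(results, key=lambda r: -r.fun)
    lls = tuple(-r.fun for r in results)
    ll, grad = _loglik_and_grad(best.x, md, k, p)
    gnorm = _projected_grad_norm(best.x, grad, bounds)
    converged = bool(np.isfinite(ll)) and gnorm < gtol
    if not converged and not any(r.success for r in results):
        raise RuntimeError(
            f"RBS fit failed to converge from {len(results)} starts; "
            f"final projected gradient norm {gnorm:.3g}; messages: "
            + "; ".join(str(r.message) for r in results))

    cov = None
    if compute_cov:
        free = np.array([lo is None or hi is None or lo != hi
                         for lo, hi in bounds])
        theta_hat = best.x.copy()

        def neg_free(tf):
            th = theta_hat.copy()
            th[free] = tf
            v, _ = neg(th)
            return v

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                H = approx_hess(theta_hat[free], neg_free)
            cov_free = np.linalg.inv(H)
            cov_free = 0.5 * (cov_free + cov_free.T)
            cov = np.zeros((theta_hat.size, theta_hat.size))
            ix = np.ix_(free, free)
            cov[ix] = cov_free
        except np.linalg.LinAlgError:
            cov = None

    params = RBSParams.unpack(best.x, k, p)
    return RBSFit(params=params, spec=spec, cov=cov, loglik=float(ll),
                  names=md.names, converged=converged, n_iter=int(best.nit),
                  grad_norm=gnorm, multistart_logliks=lls,
                  fixed_alpha=fix_alpha is not None)


# -- prediction ---------------------------------------------------------------

def _cum_excess_matrix(fit: RBSFit, times, X: np.ndarray, theta=None):
    """Cumulative excess hazard for each (subject, time) pair."""
    k = fit.params.nu.size
    p = fit.params.beta.size
    th = fit.theta if theta is None else theta
    nu, beta = th[:k], th[k:k + p]
    I = integrated_bspline_basis(fit.spec, np.asarray(times, dtype=float))
    base = I @ nu                                  # (T,)
    risk = np.exp(X @ beta) if p else np.ones(X.shape[0])  # (n,)
    return np.outer(risk, base)                    # (n, T)


def _profile_matrix(fit: RBSFit, profile=None, population: pd.DataFrame | None = None):
    if population is not None:
        return np.asarray(population[list(fit.names)], dtype=float)
    if profile is None:
        return np.zeros((1, fit.params.beta.size))
    return np.atleast_2d(np.asarray(profile, dtype=float))


def rbs_net_survival(fit: RBSFit, times, profile=None,
                     population: pd.DataFrame | None = None) -> SurvivalCurve:
    """Net survival ``exp(-Lambda_E)`` at ``times``.

    Profile mode evaluates one covariate vector; population mode averages
    individual net survivals over the rows of ``population``.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    X = _profile_matrix(fit, profile, population)
    S = np.exp(-_cum_excess_matrix(fit, times, X)).mean(axis=0)
    return SurvivalCurve(times=times, estimate=S, variance=np.full(times.size, np.nan),
                         ci_low=np.full(times.size, np.nan),
                         ci_high=np.full(times.size, np.nan),
                         estimator="rbs")


def mc_confidence(fit: RBSFit, times, profile=None,
                  population: pd.DataFrame | None = None,
                  draws: int = 1000, level: float = 0.95,
                  seed=None) -> SurvivalCurve:
    """Monte-Carlo confidence band for the net survival.

    Parameter vectors are drawn from N(theta_hat, cov), clipped to the box
    constraints, the net survival recomputed per draw and pointwise
    percentile limits returned.
    """
    if fit.cov is None:
        raise ValueError("covariance unavailable; refit with compute_cov=True "
                         "or use a bootstrap")
    rng = np.random.default_rng(seed)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    X = _profile_matrix(fit, profile, population)
    k = fit.params.nu.size
    # PSD-safe sampling: numerical Hessians can carry tiny negative eigenvalues
    w, V = np.linalg.eigh(0.5 * (fit.cov + fit.cov.T))
    A = V * np.sqrt(np.clip(w, 0.0, None))
    thetas = fit.theta + rng.standard_normal((draws, fit.theta.size)) @ A.T
    thetas[:, :k] = np.clip(thetas[:, :k], 0.0, None)
    thetas[:, -1] = np.clip(thetas[:, -1], ALPHA_FLOOR, None)
    curves = np.empty((draws, times.size))
    for b in range(draws):
        curves[b] = np.exp(-_cum_excess_matrix(fit, times, X, thetas[b])).mean(axis=0)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    point = np.exp(-_cum_excess_matrix(fit, times, X)).mean(axis=0)
    return SurvivalCurve(times=times, estimate=point,
                         variance=curves.var(axis=0, ddof=1),
                         ci_low=np.quantile(curves, lo_q, axis=0),
                         ci_high=np.quantile(curves, hi_q, axis=0),
                         estimator="rbs")


# -- sklearn-style estimator --------------------------------------------------

class RescaledBSpline(BaseEstimator):
    """Rescaled B-spline excess-hazard model as a scikit-learn estimator.

    Parameters
    ----------
    rate_table : RateTable or None
        Population expected-mortality table (scale 1; the selection scale
        ``alpha`` is estimated).
    covariates : sequence of str
        Columns of the subject table entering the excess hazard with
        proportional effects.
    knots : tuple of float
        Interior knots of the quadratic baseline spline, in years.
    boundary_max : float or None
        Right boundary knot; defaults to the largest observed time.
    fix_alpha : float or None
        Pin the selection scale instead of estimating it.
    n_starts : int
        Number of perturbed starting points for the multistart guard.
    """

    def __init__(self, rate_table=None, covariates=(), knots=(1.0, 5.0),
                 boundary_max=None, fix_alpha=None, n_starts=3,
                 mc_draws=1000, random_state=None):
        self.rate_table = rate_table
        self.covariates = covariates
        self.knots = knots
        self.boundary_max = boundary_max
        self.fix_alpha = fix_alpha
        self.n_starts = n_starts
        self.mc_draws = mc_draws
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        tmax = (float(self.boundary_max) if self.boundary_max is not None
                else float(np.max(X["time"])))
        spec = SplineSpec(interior_knots=tuple(self.knots), boundary=(0.0, tmax))
        fit = fit_rbs(X, self.rate_table, spec, covariates=tuple(self.covariates),
                      fix_alpha=self.fix_alpha, n_starts=self.n_starts)
        self.result_ = fit
        self.spec_ = spec
        self.nu_ = fit.params.nu
        self.coef_ = fit.params.beta
        self.alpha_ = fit.params.alpha
        self.cov_ = fit.cov
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        return self

    def predict_net_survival(self, times, profile=None, population=None,
                             ci: bool = False) -> SurvivalCurve:
        if ci:
            return mc_confidence(self.result_, times, profile, population,
                                 draws=self.mc_draws, seed=self.random_state)
        return rbs_net_survival(self.result_, times, profile, population)

    def summary(self) -> pd.DataFrame:
        return self.result_.summary()
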