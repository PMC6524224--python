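"""Performance criteria and the simulation-scenario runner.

The truth against which every estimator is judged is the theoretical group
net survival: the average over the group's covariate distribution of the
individual net survivals ``exp(-Lambda_0(t) exp(beta' x))``.  Per method,
misclassification condition and evaluation time (5/10/15 years by default)
the runner reports

* bias: mean(estimate - truth) over replicates,
* relative bias (%): bias / truth * 100,
* RMSE: root mean squared error,
* ECR (%): share of replicates whose 95% CI covers the truth,

plus the same criteria for the regression parameters (beta_age,
beta_treatment, alpha) of the Cox and RBS models.  Replicates whose fit
fails are dropped and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coxnet import cox_net_curve, fit_cox_excess
from .lifetable import RateTable, make_synthetic_ratetable
from .nonparam import km_net, pohar_perme, weighted_nelson_aalen
from .rbs import SplineSpec, fit_rbs, mc_confidence, rbs_net_survival
from .simulator import (BaselineSpec, ScenarioConfig, apply_misclassification,
                        assemble_trial, calibrate_baseline, calibrate_censoring,
                        substreams)

__all__ = [
    "theoretical_net_survival",
    "population_net_survival",
    "evaluate",
    "run_scenario",
    "PerformanceTable",
]

Z95 = 1.959963984540054
DEFAULT_TIMES = (5.0, 10.0, 15.0)


def theoretical_net_survival(covariates: pd.DataFrame, baseline: BaselineSpec,
                             beta_age: float, beta_treatment: float, t):
    """Group-average theoretical net survival over given covariate rows."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    eta = (beta_age * np.asarray(covariates["age_c"], dtype=float)
           + beta_treatment * np.asarray(covariates["treatment"], dtype=float))
    lam0 = np.atleast_1d(baseline.cumhaz(t))
    out = np.exp(-np.outer(np.exp(eta), lam0)).mean(axis=0)
    return float(out[0]) if out.size == 1 and np.isscalar(t) else out


def population_net_survival(baseline: BaselineSpec, beta_age: float,
                            beta_treatment: float, t, group: str = "placebo",
                            age_mixture=None):
    """Theoretical net survival over the age *law* (quadrature, no sampling)."""
    from .simulator import DEFAULT_AGE_MIXTURE
    mix = DEFAULT_AGE_MIXTURE if age_mixture is None else age_mixture
    t = np.atleast_1d(np.asarray(t, dtype=float))
    nodes, weights = mix.quadrature()
    z = 1.0 if group == "treatment" else 0.0
    risk = np.exp(beta_age * (nodes - mix.mean) + beta_treatment * z)
    lam0 = np.atleast_1d(baseline.cumhaz(t))
    out = np.exp(-np.outer(lam0, risk)) @ weights
    return float(out[0]) if out.size == 1 else out


def evaluate(estimates, truth, ci_low=None, ci_high=None):
    """Bias, relative bias (%), RMSE and ECR (%) per the displayed formulas.

    ``estimates`` may contain NaN for failed replicates; these are dropped
    and counted in ``n_failed``.
    """
    est = np.asarray(estimates, dtype=float)
    ok = np.isfinite(est)
    if not np.any(ok):
        raise ValueError("all replicates failed")
    est = est[ok]
    err = est - truth
    bias = float(np.mean(err))
    out = {
        "bias": bias,
        "rbias": bias / truth * 100.0,
        "rmse": float(np.sqrt(np.mean(err ** 2))),
        "ecr": np.nan,
        "n_used": int(est.size),
        "n_failed": int((~ok).sum()),
    }
    if ci_low is not None and ci_high is not None:
        lo = np.asarray(ci_low, dtype=float)[ok]
        hi = np.asarray(ci_high, dtype=float)[ok]
        have = np.isfinite(lo) & np.isfinite(hi)
        if np.any(have):
            out["ecr"] = float(np.mean((lo[have] <= truth) & (truth <= hi[have])) * 100.0)
    return out


@dataclass
class PerformanceTable:
    """Simulation-study report: net-survival and parameter criteria."""

    survival: pd.DataFrame
    parameters: pd.DataFrame
    truth: dict
    n_replicates: int

    def warn_banner(self, threshold: float = 0.05):
        frac = self.survival["n_failed"] / (self.survival["n_used"]
                                            + self.survival["n_failed"])
        if (frac > threshold).any():
            return ("WARNING: more than {:.0%} of replicate fits failed for "
                    "some method".format(threshold))
        return None


ALL_METHODS = ("gs", "km", "cox", "wna", "pp", "rbs")
CAUSE_SPECIFIC = {"km", "cox", "wna"}


def run_scenario(
    config: ScenarioConfig,
    methods=ALL_METHODS,
    misclass_rates=(0.0,),
    seed=None,
    rt: RateTable | None = None,
    baseline: BaselineSpec | None = None,
    times=DEFAULT_TIMES,
    group: str = "placebo",
    knots=(1.0, 5.0),
    cox_bootstrap: int = 0,
    rbs_mc_draws: int = 500,
    progress: bool = False,
) -> PerformanceTable:
    """Run one scenario and aggregate the four performance criteria.

    The gold standard (``gs``) applies Kaplan-Meier to the net-setting data
    (T_N, status_net); cause-specific methods see the observed cause under
    each misclassification rate; Pohar-Perme and the RBS model use vital
    status only and are therefore identical across misclassification
    conditions (they are evaluated once, at condition 0).
    """
    if rt is None:
        rt = make_synthetic_ratetable()
    if baseline is None:
        baseline = calibrate_baseline(beta_age=config.beta_age,
                                      beta_treatment=config.beta_treatment,
                                      age_mixture=config.age_mixture)
    times = np.asarray(times, dtype=float)
    truth = {float(t): population_net_survival(
        baseline, config.beta_age, config.beta_treatment, t, group=group,
        age_mixture=config.age_mixture) for t in times}

    root = np.random.SeedSequence(seed)
    cal_seed, rep_root = root.spawn(2)
    b = calibrate_censoring(config, baseline, rt,
                            seed=cal_seed.generate_state(1)[0] % (2 ** 31))
    rep_seeds = [s.generate_state(1)[0] % (2 ** 31)
                 for s in rep_root.spawn(config.replicates)]

    records = {}      # (method, rate) -> {t: [est...], ...}
    cis = {}
    par_records = {}  # (method, rate, param) -> ([est], [lo], [hi])

    def push(method, rate, curve_vals, curve_cis):
        key = (method, rate)
        rec = records.setdefault(key, {float(t): [] for t in times})
        civ = cis.setdefault(key, {float(t): [] for t in times})
        for t in times:
            rec[float(t)].append(curve_vals.get(float(t), np.nan))
            civ[float(t)].append(curve_cis.get(float(t), (np.nan, np.nan)))

    def push_params(method, rate, entries):
        for name, est, lo, hi in entries:
            par_records.setdefault((method, rate, name), []).append((est, lo, hi))

    spec = SplineSpec(interior_knots=tuple(knots),
                      boundary=(0.0, float(config.admin_horizon)))

    for r, rseed in enumerate(rep_seeds):
        data = assemble_trial(config, baseline, rt, seed=rseed, b=b)
        sub = data[data["treatment"] == (1 if group == "treatment" else 0)]

        def curve_to_points(curve):
            vals = {float(t): float(curve.at(t)) for t in times}
            lo, hi = curve.ci_at(times)
            cisd = {float(t): (float(lo[i]), float(hi[i]))
                    for i, t in enumerate(times)}
            return vals, cisd

        if "gs" in methods:
            gs_view = sub.rename(columns={"time": "_t", "status": "_s"}).rename(
                columns={"T_N": "time", "status_net": "status"})
            gs_view = gs_view.assign(cause=gs_view["status"])
            try:
                push("gs", 0.0, *curve_to_points(km_net(gs_view)))
            except ValueError:
                push("gs", 0.0, {}, {})
        if "pp" in methods:
            try:
                push("pp", 0.0, *curve_to_points(pohar_perme(sub, rt)))
            except Exception:
                push("pp", 0.0, {}, {})
        if "rbs" in methods:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_rbs(data, rt, spec,
                                  covariates=("treatment", "age_c"))
                if rbs_mc_draws > 0 and fit.cov is not None:
                    curve = mc_confidence(fit, times, population=sub,
                                          draws=rbs_mc_draws, seed=rseed)
                else:
                    curve = rbs_net_survival(fit, times, population=sub)
                vals = {float(t): float(curve.estimate[i])
                        for i, t in enumerate(times)}
                cisd = {float(t): (float(curve.ci_low[i]), float(curve.ci_high[i]))
                        for i, t in enumerate(times)}
                push("rbs", 0.0, vals, cisd)
                se = (np.sqrt(np.diag(fit.cov)) if fit.cov is not None
                      else np.full(fit.theta.size, np.nan))
                k = fit.params.nu.size
                push_params("rbs", 0.0, [
                    ("beta_treatment", fit.params.beta[0],
                     fit.params.beta[0] - Z95 * se[k],
                     fit.params.beta[0] + Z95 * se[k]),
                    ("beta_age", fit.params.beta[1],
                     fit.params.beta[1] - Z95 * se[k + 1],
                     fit.params.beta[1] + Z95 * se[k + 1]),
                    ("alpha", fit.params.alpha,
                     fit.params.alpha - Z95 * se[-1],
                     fit.params.alpha + Z95 * se[-1]),
                ])
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                push("rbs", 0.0, {}, {})

        for rate in misclass_rates:
            if not (set(methods) & CAUSE_SPECIFIC):
                continue
            view = (data if rate == config.misclass_rate else
                    apply_misclassification(
                        data, rate, config.misclass_after,
                        np.random.default_rng(
                            np.random.SeedSequence([int(rseed), int(rate * 1000), 7])
                        )))
            sview = view[view["treatment"] == (1 if group == "treatment" else 0)]
            if "km" in methods:
                try:
                    push("km", rate, *curve_to_points(km_net(sview)))
                except ValueError:
                    push("km", rate, {}, {})
            if "wna" in methods:
                try:
                    push("wna", rate, *curve_to_points(
                        weighted_nelson_aalen(sview, rt)))
                except Exception:
                    push("wna", rate, {}, {})
            if "cox" in methods:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        cfit = fit_cox_excess(view, ("treatment", "age_c"))
                        curve = cox_net_curve(cfit, sview, times,
                                              bootstrap=cox_bootstrap,
                                              fit_data=view, seed=rseed)
                    push("cox", rate, *curve_to_points(curve))
                    se = np.sqrt(np.diag(cfit.cov_beta))
                    push_params("cox", rate, [
                        ("beta_treatment", cfit.beta[0],
                         cfit.beta[0] - Z95 * se[0], cfit.beta[0] + Z95 * se[0]),
                        ("beta_age", cfit.beta[1],
                         cfit.beta[1] - Z95 * se[1], cfit.beta[1] + Z95 * se[1]),
                    ])
                except (RuntimeError, ValueError, np.linalg.LinAlgError):
                    push("cox", rate, {}, {})
        if progress and (r + 1) % 50 == 0:
            print(f"  replicate {r + 1}/{config.replicates}")

    rows = []
    for (method, rate), rec in records.items():
        for t in times:
            vals = rec[float(t)]
            ci_pairs = cis[(method, rate)][float(t)]
            lo = [c[0] for c in ci_pairs]
            hi = [c[1] for c in ci_pairs]
            try:
                stats = evaluate(vals, truth[float(t)], lo, hi)
            except ValueError:
                stats = {"bias": np.nan, "rbias": np.nan, "rmse": np.nan,
                         "ecr": np.nan, "n_used": 0, "n_failed": len(vals)}
            rows.append({"method": method, "misclass": rate, "time": float(t),
                         **stats})
    survival = pd.DataFrame(rows)

    par_truth = {"beta_age": config.beta_age,
                 "beta_treatment": config.beta_treatment,
                 "alpha": config.alpha}
    prow = []
    for (method, rate, name), triples in par_records.items():
        est = [x[0] for x in triples]
        lo = [x[1] for x in triples]
        hi = [x[2] for x in triples]
        stats = evaluate(est, par_truth[name], lo, hi)
        prow.append({"method": method, "misclass": rate, "param": name,
                     "mean": float(np.nanmean(est)), **stats})
    parameters = pd.DataFrame(prow)
    return PerformanceTable(survival=survival, parameters=parameters,
                            truth=truth, n_replicates=config.replicates)
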