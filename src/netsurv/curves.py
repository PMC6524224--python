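"""Survival-curve container shared by all estimators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SurvivalCurve"]


@dataclass
class SurvivalCurve:
    """A net-survival step curve (or smooth curve on a grid).

    ``estimate(0) = 1`` implicitly: evaluation before the first stored time
    returns 1.  Estimates from weighted estimators may locally exceed 1 or
    be non-monotone; they are reported uncapped unless ``cap`` is used.
    """

    times: np.ndarray
    estimate: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    estimator: str = ""
    at_risk: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.estimate = np.asarray(self.estimate, dtype=float)
        order = np.argsort(self.times, kind="stable")
        if np.any(order != np.arange(order.size)):
            raise ValueError("curve times must be ascending")

    def at(self, t):
        """Last-value-carried-forward evaluation; 1 before the first time."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.ones_like(t)
            return float(out) if out.ndim == 0 else out
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.estimate[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out

    def ci_at(self, t):
        """(lo, hi) carried forward; (1, 1) before the first time."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            return np.ones_like(t), np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        lo = np.where(idx >= 0, self.ci_low[np.clip(idx, 0, None)], 1.0)
        hi = np.where(idx >= 0, self.ci_high[np.clip(idx, 0, None)], 1.0)
        return lo, hi

    def capped(self) -> "SurvivalCurve":
        """Copy with the estimate (and CI) capped at 1 from above."""
        return SurvivalCurve(
            times=self.times,
            estimate=np.minimum(self.estimate, 1.0),
            variance=self.variance,
            ci_low=np.minimum(self.ci_low, 1.0),
            ci_high=np.minimum(self.ci_high, 1.0),
            estimator=self.estimator,
            at_risk=self.at_risk,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "estimate": self.estimate,
                "var": self.variance,
                "lo": self.ci_low,
                "hi": self.ci_high,
            }
        )
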