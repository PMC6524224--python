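"""Population life tables as rate tables.

A rate table stores the expected (general-population, all-cause) mortality
hazard ``lambda_P`` on a grid of attained age x calendar year x sex.  Rates
are annual hazards per person-year, piecewise constant on each
``[age, age+1) x [year, year+1)`` cell.  A subject diagnosed at (fractional)
age ``a0`` in (fractional) calendar year ``y0`` moves along the diagonal of
the Lexis diagram: at follow-up time ``t`` the attained age is ``a0 + t`` and
the attained year is ``y0 + t``.  Cumulative expected hazard is the exact
integral of the piecewise-constant hazard along that diagonal, with band
boundaries at every integer age and integer year crossing.

All trajectory routines are vectorized over subjects; scalar inputs are
accepted and return scalars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RateTable",
    "Demographics",
    "read_ratetable",
    "write_ratetable",
    "expected_hazard",
    "cumulative_expected_hazard",
    "invert_cumulative_hazard",
    "make_synthetic_ratetable",
]

DAYS_PER_YEAR = 365.25


class RateTableCoverageError(ValueError):
    """A trajectory left the age x year span of the rate table."""


@dataclass(frozen=True)
class Demographics:
    """Demographic profile at diagnosis used to match a subject to the table.

    ``age`` and ``year`` may be fractional; ``sex`` must be one of the
    table's sex labels.
    """

    age: float
    sex: str
    year: float

    def __post_init__(self):
        if self.age < 0:
            raise ValueError(f"age_at_diagnosis must be >= 0, got {self.age}")


@dataclass
class RateTable:
    """Expected-mortality hazard grid.

    Parameters
    ----------
    ages : 1-d int array, ascending and contiguous
    years : 1-d int array, ascending and contiguous
    sexes : sequence of category labels
    rate : array of shape (n_ages, n_years, n_sexes), annual hazards >= 0
    """

    ages: np.ndarray
    years: np.ndarray
    sexes: tuple
    rate: np.ndarray
    clamp_oldest: bool = field(default=False)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        self.sexes = tuple(self.sexes)
        self.rate = np.asarray(self.rate, dtype=float)
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("age grid must be ascending and contiguous")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("year grid must be ascending and contiguous")
        expected_shape = (self.ages.size, self.years.size, len(self.sexes))
        if self.rate.shape != expected_shape:
            raise ValueError(
                f"rate grid has shape {self.rate.shape}, expected {expected_shape}"
            )
        if not np.all(np.isfinite(self.rate)) or np.any(self.rate < 0):
            raise ValueError("all rates must be finite and >= 0")

    # -- indexing helpers ---------------------------------------------------
    def sex_index(self, sex) -> np.ndarray:
        """Map sex labels (scalar or array) to grid indices."""
        lookup = {s: i for i, s in enumerate(self.sexes)}
        if np.isscalar(sex) or isinstance(sex, str):
            try:
                return lookup[sex]
            except KeyError:
                raise KeyError(f"unknown sex label {sex!r}; table has {self.sexes}")
        return np.asarray([lookup[s] for s in np.asarray(sex, dtype=object)])

    def _age_idx(self, attained_age):
        idx = np.floor(attained_age).astype(int) - self.ages[0]
        if self.clamp_oldest:
            idx = np.minimum(idx, self.ages.size - 1)
        return idx

    def _check_range(self, age_idx, year_idx, context=""):
        bad_age = (age_idx < 0) | (age_idx >= self.ages.size)
        bad_year = (year_idx < 0) | (year_idx >= self.years.size)
        if np.any(bad_age) or np.any(bad_year):
            raise RateTableCoverageError(
                f"trajectory outside rate-table span {context}"
                f" (ages {self.ages[0]}..{self.ages[-1]},"
                f" years {self.years[0]}..{self.years[-1]})"
            )

    # -- pointwise lookup ---------------------------------------------------
    def hazard(self, age, year, sex, scale=1.0):
        """Annual hazard of the cell containing (floor(age), floor(year), sex),
        multiplied by ``scale``."""
        age = np.asarray(age, dtype=float)
        year = np.asarray(year, dtype=float)
        age_idx = self._age_idx(age)
        year_idx = np.floor(year).astype(int) - self.years[0]
        self._check_range(age_idx, year_idx, context=f"at age {age}, year {year}")
        out = scale * self.rate[age_idx, year_idx, self.sex_index(sex)]
        return out

    # -- Lexis band decomposition ------------------------------------------
    def _bands(self, age0, year0, sex_idx, t_stop):
        """Band edges and per-band rates along the Lexis diagonal.

        Returns ``(edges, rates)`` with ``edges`` of shape (n, m+1) and
        ``rates`` of shape (n, m); zero-width bands carry rate 0.
        """
        age0 = np.atleast_1d(np.asarray(age0, dtype=float))
        year0 = np.atleast_1d(np.asarray(year0, dtype=float))
        t_stop = np.atleast_1d(np.asarray(t_stop, dtype=float))
        sex_idx = np.broadcast_to(np.atleast_1d(sex_idx), age0.shape)
        if np.any(t_stop < 0) or not np.all(np.isfinite(t_stop)):
            raise ValueError("follow-up time must be finite and >= 0")
        n = age0.size
        k_max = int(np.ceil(t_stop.max())) + 1 if t_stop.size else 0
        ks = np.arange(1, k_max + 1)
        # integer-crossing offsets for age and calendar year
        cross_a = (np.floor(age0)[:, None] + ks) - age0[:, None]
        cross_y = (np.floor(year0)[:, None] + ks) - year0[:, None]
        edges = np.concatenate(
            [np.zeros((n, 1)), cross_a, cross_y, t_stop[:, None]], axis=1
        )
        edges = np.clip(edges, 0.0, t_stop[:, None])
        edges.sort(axis=1)
        widths = np.diff(edges, axis=1)
        mids = 0.5 * (edges[:, :-1] + edges[:, 1:])
        live = widths > 0
        rates = np.zeros_like(widths)
        if np.any(live):
            age_idx = self._age_idx(age0[:, None] + mids)
            year_idx = np.floor(year0[:, None] + mids).astype(int) - self.years[0]
            self._check_range(age_idx[live], year_idx[live])
            sex_b = np.broadcast_to(sex_idx[:, None], widths.shape)
            rates[live] = self.rate[age_idx[live], year_idx[live], sex_b[live]]
        return edges, rates

    def cumulative_hazard(self, age0, year0, sex, t, scale=1.0):
        """Exact ``scale * integral_0^t lambda_P(a0+u, y0+u) du`` per subject."""
        scalar = np.isscalar(t) and np.isscalar(age0)
        sex_idx = self.sex_index(sex)
        edges, rates = self._bands(age0, year0, sex_idx, t)
        out = scale * np.sum(rates * np.diff(edges, axis=1), axis=1)
        return float(out[0]) if scalar else out

    def cumulative_hazard_edges(self, age0, year0, sex, t_stop, scale=1.0):
        """Band edges and cumulative hazard at each edge (for interpolation)."""
        sex_idx = self.sex_index(sex)
        edges, rates = self._bands(age0, year0, sex_idx, t_stop)
        cum = np.concatenate(
            [np.zeros((edges.shape[0], 1)),
             np.cumsum(scale * rates * np.diff(edges, axis=1), axis=1)],
            axis=1,
        )
        return edges, cum

    def coverage_horizon(self, age0, year0):
        """Largest follow-up time still inside the grid for each subject."""
        age0 = np.asarray(age0, dtype=float)
        year0 = np.asarray(year0, dtype=float)
        return np.minimum(self.ages[-1] + 1 - age0, self.years[-1] + 1 - year0)

    def invert_cumulative_hazard(self, age0, year0, sex, target, scale=1.0):
        """Solve ``scale * Lambda_P(t) = target`` for t, band by band.

        Where the target exceeds the cumulative hazard accumulated over the
        whole covered trajectory, ``inf`` is returned (the event falls beyond
        table coverage).
        """
        scalar = np.isscalar(target) and np.isscalar(age0)
        age0 = np.atleast_1d(np.asarray(age0, dtype=float))
        year0 = np.atleast_1d(np.asarray(year0, dtype=float))
        target = np.atleast_1d(np.asarray(target, dtype=float))
        if age0.size == 1 and target.size > 1:
            age0 = np.repeat(age0, target.size)
            year0 = np.repeat(year0, target.size)
        horizon = self.coverage_horizon(age0, year0)
        sex_idx = self.sex_index(sex)
        edges, rates = self._bands(age0, year0, sex_idx, horizon)
        cum = np.concatenate(
            [np.zeros((edges.shape[0], 1)),
             np.cumsum(scale * rates * np.diff(edges, axis=1), axis=1)],
            axis=1,
        )
        n = edges.shape[0]
        t = np.full(n, np.inf)
        total = cum[:, -1]
        reachable = target <= total
        for i in np.nonzero(reachable)[0]:
            j = int(np.searchsorted(cum[i], target[i], side="left"))
            if j == 0:
                t[i] = 0.0
                continue
            j -= 1  # band index whose right-edge cumhaz >= target
            r = scale * rates[i, j]
            if r <= 0:  # flat band: jump to its right edge
                t[i] = edges[i, j + 1]
            else:
                t[i] = edges[i, j] + (target[i] - cum[i, j]) / r
        return float(t[0]) if scalar else t


# -- functional wrappers on (RateTable, Demographics) -------------------------

def expected_hazard(rt: RateTable, d: Demographics, t, scale: float = 1.0):
    """Rescaled expected hazard ``scale * lambda_P`` at follow-up time ``t``."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    return rt.hazard(d.age + np.asarray(t), d.year + np.asarray(t), d.sex, scale)


def cumulative_expected_hazard(rt: RateTable, d: Demographics, t, scale: float = 1.0):
    """Rescaled cumulative expected hazard ``scale * Lambda_P(t)``."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    return rt.cumulative_hazard(d.age, d.year, d.sex, t, scale)


def invert_cumulative_hazard(rt: RateTable, d: Demographics, target, scale: float = 1.0):
    """Time ``t`` with ``scale * Lambda_P(t) = target`` (inf beyond coverage)."""
    return rt.invert_cumulative_hazard(d.age, d.year, d.sex, target, scale)


# -- I/O ----------------------------------------------------------------------

REQUIRED_COLUMNS = ("age", "year", "sex", "rate")


def read_ratetable(source, sep: str = ",", clamp_oldest: bool = False) -> RateTable:
    """Read a long-format rate table (columns age, year, sex, rate).

    One row per grid cell; the grid must be complete.  Rates are annual
    hazards.  Tables published as daily hazards must be multiplied by 365.25
    before import (see the converter note in the package docs).
    """
    df = pd.read_csv(source, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rate table missing column(s): {missing}")
    dup = df.duplicated(subset=["age", "year", "sex"])
    if dup.any():
        first = df.loc[dup.idxmax(), ["age", "year", "sex"]].tolist()
        raise ValueError(f"duplicated rate-table cell {tuple(first)}")
    if (df["rate"] < 0).any():
        raise ValueError("negative rate in rate table")
    ages = np.sort(df["age"].unique())
    years = np.sort(df["year"].unique())
    sexes = tuple(pd.unique(df["sex"]))  # order of first appearance
    n_expected = ages.size * years.size * len(sexes)
    if len(df) != n_expected:
        present = set(map(tuple, df[["age", "year", "sex"]].itertuples(index=False)))
        for a in ages:
            for y in years:
                for s in sexes:
                    if (a, y, s) not in present:
                        raise ValueError(f"missing rate-table cell (age={a}, year={y}, sex={s!r})")
    grid = (
        df.set_index(["age", "year", "sex"])["rate"]
        .unstack("sex")
        .loc[:, list(sexes)]
        .to_numpy()
        .reshape(ages.size, years.size, len(sexes))
    )
    return RateTable(ages=ages, years=years, sexes=sexes, rate=grid,
                     clamp_oldest=clamp_oldest)


def write_ratetable(rt: RateTable, dest, sep: str = ",") -> None:
    """Write a RateTable in the long format read by :func:`read_ratetable`."""
    a, y, s = np.meshgrid(rt.ages, rt.years, np.arange(len(rt.sexes)), indexing="ij")
    df = pd.DataFrame(
        {
            "age": a.ravel(),
            "year": y.ravel(),
            "sex": np.asarray(rt.sexes, dtype=object)[s.ravel()],
            "rate": rt.rate.ravel(),
        }
    )
    df.to_csv(dest, sep=sep, index=False)


def make_synthetic_ratetable(
    a0: float = 1.5e-5,
    b: float = 0.10,
    ages=range(0, 106),
    years=range(1985, 2011),
    sexes=("male", "female"),
) -> RateTable:
    """Gompertz-shaped synthetic life table: rate(age) = a0 * exp(b * age).

    Rates are constant across calendar years and sexes.  The defaults track
    French period mortality of the early 1990s at the lighter (female)
    level — about 0.0008/y at 40, 0.003/y at 53, 0.017/y at 70, 0.075/y at
    85 — which reproduces the expected-mortality burden of the national life
    table that backs the simulation design (see the methods note for the
    calibration rationale).
    """
    if a0 <= 0:
        raise ValueError("a0 must be > 0")
    ages = np.asarray(list(ages), dtype=int)
    years = np.asarray(list(years), dtype=int)
    col = a0 * np.exp(b * ages.astype(float))
    grid = np.repeat(col[:, None, None], years.size, axis=1)
    grid = np.repeat(grid, len(sexes), axis=2)
    return RateTable(ages=ages, years=years, sexes=tuple(sexes), rate=grid)
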