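"""Life-table population-growth analysis for adult female cohorts.

From daily records of a cohort (females alive, eggs laid) plus strain-level
egg viability and offspring sex ratio, this module builds the classical
survivorship/fecundity schedule

    l_x  = fraction of females alive at age x (days, adult day 1 = first census),
    m_x  = daughters born per surviving female at age x
         = (eggs(x) * egg_viability / n_alive(x)) * sex_ratio_female,

and computes the net reproductive rate R0 = sum(l_x m_x), the intrinsic rate
of increase r solving the Euler-Lotka equation sum(exp(-r x) l_x m_x) = 1,
the mean generation length T = ln(R0)/r, and the fitness-cost ratio
1 - R0_resistant / R0_susceptible.  A two-way fixed-effects ANOVA with an
interaction term tests whether the costs of two resistance mechanisms combine
additively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DegenerateInputError, DesignError, NoRootError, ValidationError


@dataclass(frozen=True)
class DailyCohortRecord:
    """One day's census of an adult female cohort: age (days), females alive, eggs laid."""

    day: int
    n_alive: int
    eggs: float

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValidationError("day index is 1-based")
        if self.n_alive < 0 or self.eggs < 0:
            raise ValidationError("n_alive and eggs must be non-negative")


@dataclass(frozen=True)
class StrainVitals:
    """Strain-level constants applied across ages: egg viability, sex ratio, cohort size."""

    egg_viability: float
    sex_ratio_female: float
    n0: int

    def __post_init__(self) -> None:
        for name in ("egg_viability", "sex_ratio_female"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.n0 < 0:
            raise ValidationError("n0 must be non-negative")


@dataclass(frozen=True)
class LifeSchedule:
    ages: tuple[int, ...]
    l_x: tuple[float, ...]
    m_x: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.ages) == len(self.l_x) == len(self.m_x)):
            raise ValidationError("ages, l_x, m_x must have equal length")
        lx = np.asarray(self.l_x)
        if lx.size and (lx.min() < 0 or lx.max() > 1 or np.any(np.diff(lx) > 1e-12)):
            raise ValidationError("l_x must lie in [0,1] and be non-increasing")
        if any(m < 0 for m in self.m_x):
            raise ValidationError("m_x must be non-negative")


@dataclass(frozen=True)
class GrowthSummary:
    """Per-replicate growth components: R0, r per day, T in days."""

    replicate: str
    R0: float
    r: float | None
    T: float | None


def build_schedule(records: Sequence[DailyCohortRecord], vitals: StrainVitals) -> LifeSchedule:
    """Survivorship and daughters-per-female schedule from daily cohort records.

    ``l_x = n_alive(x) / n0``; ``m_x`` uses the number of females alive on day
    x (not the initial cohort) as denominator. The schedule terminates at the
    first day with no survivors.
    """
    if not records:
        raise DegenerateInputError("no daily records")
    if vitals.n0 == 0:
        raise DegenerateInputError("initial cohort size is 0")
    days = [r.day for r in records]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValidationError("day must be strictly increasing")
    ages, lx, mx = [], [], []
    for rec in records:
        if rec.n_alive == 0:
            if rec.eggs > 0:
                raise ValidationError(f"day {rec.day}: eggs recorded with no females alive")
            break
        if rec.n_alive > vitals.n0:
            raise ValidationError(f"day {rec.day}: more females alive than the initial cohort")
        ages.append(rec.day)
        lx.append(rec.n_alive / vitals.n0)
        mx.append((rec.eggs * vitals.egg_viability / rec.n_alive) * vitals.sex_ratio_female)
    return LifeSchedule(tuple(ages), tuple(lx), tuple(mx))


def net_reproductive_rate(s: LifeSchedule) -> float:
    """R0 = sum over ages of l_x m_x (expected daughters per newly-adult female)."""
    return float(np.dot(s.l_x, s.m_x))


def intrinsic_rate(s: LifeSchedule, tol: float = 1e-10) -> float:
    """Solve the Euler-Lotka equation sum(exp(-r x) l_x m_x) = 1 for r.

    f(r) = sum(exp(-r x) l_x m_x) - 1 is strictly decreasing in r (ages are
    positive), so the root is unique; it is bracketed by geometric expansion
    from [-1, 1] and polished with Brent's method.
    """
    x = np.asarray(s.ages, dtype=float)
    lm = np.asarray(s.l_x) * np.asarray(s.m_x)
    if lm.sum() <= 0:
        raise NoRootError("R0 = 0: the cohort cannot replace itself at any growth rate")

    def f(r: float) -> float:
        # overflow to +inf during bracket expansion is harmless: it only
        # confirms f(lo) > 0
        with np.errstate(over="ignore"):
            return float(np.sum(np.exp(-r * x) * lm) - 1.0)

    lo, hi = -1.0, 1.0
    for _ in range(200):
        if f(hi) <= 0:
            break
        hi *= 2
    for _ in range(200):
        if f(lo) >= 0:
            break
        lo *= 2
    return float(optimize.brentq(f, lo, hi, xtol=tol))


def generation_time(R0: float, r: float) -> float:
    """Mean generation length T = ln(R0) / r (days)."""
    if R0 <= 0:
        raise ValidationError("R0 must be positive")
    if r == 0:
        raise ValidationError("T is undefined at r = 0 (R0 = 1); report the mean age of reproduction instead")
    return math.log(R0) / r


def growth_summary(records: Sequence[DailyCohortRecord], vitals: StrainVitals, replicate: str = "") -> GrowthSummary:
    """R0, r and T for one cohort replicate (r and T omitted when R0 = 0)."""
    s = build_schedule(records, vitals)
    R0 = net_reproductive_rate(s)
    if R0 <= 0:
        return GrowthSummary(replicate=replicate, R0=R0, r=None, T=None)
    r = intrinsic_rate(s)
    T = generation_time(R0, r) if r != 0 else None
    return GrowthSummary(replicate=replicate, R0=R0, r=r, T=T)


def fitness_cost_ratio(R0_resistant: float, R0_susceptible: float) -> float:
    """1 - R0_resistant / R0_susceptible; positive values mean resistance is costly."""
    if R0_susceptible <= 0:
        raise ValidationError("susceptible R0 must be positive")
    return 1.0 - R0_resistant / R0_susceptible


def additivity_anova(values: pd.DataFrame, response: str = "value") -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction on a balanced 2x2 design.

    ``values`` needs columns ``kdr`` and ``cyp`` (each coded 0/1) and the
    response.  The interaction F tests departure from additivity of the two
    resistance mechanisms.  The design must be balanced with >= 2 replicates
    per cell (sums of squares of all types coincide on a balanced design, so
    the classical sequential decomposition is used).  Returns a table with
    sum_sq, df, F and PR(>F) rows for kdr, cyp, kdr:cyp and Residual; if the
    residual mean square is 0 (all values equal within cells) the F columns
    are NaN and a ``degenerate`` attribute is set.
    """
    for col in ("kdr", "cyp", response):
        if col not in values.columns:
            raise DesignError(f"missing column '{col}'")
    sizes = values.groupby(["kdr", "cyp"]).size()
    if len(sizes) != 4:
        raise DesignError("all four kdr x cyp cells must be populated")
    if sizes.min() < 2:
        raise DesignError("need >= 2 replicates per cell")
    if sizes.nunique() != 1:
        raise DesignError("design must be balanced (equal replicates per cell)")

    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = values.rename(columns={response: "_y"})
    model = ols("_y ~ C(kdr) * C(cyp)", data=df).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        table = sm.stats.anova_lm(model, typ=1)
    table.index = ["kdr", "cyp", "kdr:cyp", "Residual"]
    table.attrs["degenerate"] = bool(np.isclose(table.loc["Residual", "sum_sq"], 0.0))
    return table


def kaplan_meier_survivorship(
    records: Sequence[DailyCohortRecord],
    n0: int,
    censored_at: int | None = None,
) -> pd.DataFrame:
    """Kaplan-Meier survival curve from daily census counts.

    Deaths on day x are the drop from the previous day's count.  Without
    censoring this product-limit estimate equals the raw survivorship l_x from
    :func:`build_schedule`; ``censored_at`` right-censors animals still alive
    on that day (for generality).  Returns a DataFrame with columns ``day``
    and ``survival``.
    """
    from lifelines import KaplanMeierFitter

    durations, observed = [], []
    prev = n0
    for rec in records:
        deaths = prev - rec.n_alive
        if deaths < 0:
            raise ValidationError(f"day {rec.day}: n_alive increased")
        durations.extend([rec.day] * deaths)
        observed.extend([1] * deaths)
        prev = rec.n_alive
        if censored_at is not None and rec.day >= censored_at:
            break
    if prev > 0:
        last_day = records[-1].day if censored_at is None else censored_at
        durations.extend([last_day] * prev)
        observed.extend([0] * prev)
    km = KaplanMeierFitter()
    km.fit(durations, event_observed=observed, timeline=[r.day for r in records])
    sf = km.survival_function_.reset_index()
    sf.columns = ["day", "survival"]
    return sf
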