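"""Life-table schedules, R0, Euler-Lotka solver, cost ratio, ANOVA, Kaplan-Meier."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import kdrcost as k
from kdrcost.errors import DegenerateInputError, DesignError, NoRootError, ValidationError

GOLDEN = (1 + math.sqrt(5)) / 2


def make_schedule(ages, lx, mx):
    return k.LifeSchedule(tuple(ages), tuple(lx), tuple(mx))


class TestBuildSchedule:
    def test_direct_arithmetic(self):
        vitals = k.StrainVitals(egg_viability=0.75, sex_ratio_female=0.5, n0=50)
        records = [k.DailyCohortRecord(day=5, n_alive=40, eggs=400)]
        s = k.build_schedule(records, vitals)
        assert s.l_x == (0.8,)
        assert s.m_x[0] == pytest.approx((400 * 0.75 / 40) * 0.5)  # 3.75 daughters

    def test_zero_eggs(self):
        vitals = k.StrainVitals(0.9, 0.5, 10)
        records = [k.DailyCohortRecord(d, 10 - d, 0) for d in range(1, 5)]
        s = k.build_schedule(records, vitals)
        assert all(m == 0 for m in s.m_x)

    def test_terminates_at_extinction(self):
        vitals = k.StrainVitals(0.9, 0.5, 10)
        records = [
            k.DailyCohortRecord(1, 10, 100),
            k.DailyCohortRecord(2, 0, 0),
            k.DailyCohortRecord(3, 0, 0),
        ]
        s = k.build_schedule(records, vitals)
        assert s.ages == (1,)

    def test_eggs_without_females_rejected(self):
        vitals = k.StrainVitals(0.9, 0.5, 10)
        with pytest.raises(ValidationError):
            k.build_schedule(
                [k.DailyCohortRecord(1, 10, 0), k.DailyCohortRecord(2, 0, 50)], vitals
            )

    def test_empty_cohort_rejected(self):
        with pytest.raises(DegenerateInputError):
            k.build_schedule([], k.StrainVitals(0.9, 0.5, 10))


class TestGrowthRates:
    def test_r0_single_age(self):
        assert k.net_reproductive_rate(make_schedule([1], [1.0], [2.0])) == 2.0

    def test_r0_zero(self):
        s = make_schedule([1, 2], [1.0, 0.5], [0.0, 0.0])
        assert k.net_reproductive_rate(s) == 0.0
        with pytest.raises(NoRootError):
            k.intrinsic_rate(s)

    def test_euler_lotka_closed_form_exponential(self):
        # l*m = e at age 1: exp(-r) e = 1 so r = 1 exactly
        r = k.intrinsic_rate(make_schedule([1], [1.0], [math.e]))
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_euler_lotka_golden_ratio(self):
        # unit l*m at ages 1 and 2: exp(-r) + exp(-2r) = 1, a quadratic in
        # exp(-r) with root 1/phi, so r = ln(phi)
        r = k.intrinsic_rate(make_schedule([1, 2], [1.0, 1.0], [1.0, 1.0]))
        assert r == pytest.approx(math.log(GOLDEN), abs=1e-8)

    def test_replacement_gives_zero(self):
        r = k.intrinsic_rate(make_schedule([3], [0.5], [2.0]))  # R0 = 1
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_root_satisfies_equation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ages = np.arange(1, rng.integers(2, 30))
            lx = np.cumprod(rng.uniform(0.7, 1.0, size=len(ages)))
            mx = rng.uniform(0, 5, size=len(ages))
            if (lx * mx).sum() == 0:
                continue
            s = make_schedule(ages, lx, mx)
            r = k.intrinsic_rate(s)
            resid = sum(math.exp(-r * x) * l * m for x, l, m in zip(ages, lx, mx)) - 1
            assert abs(resid) < 1e-9
            # sign of r matches net reproduction
            R0 = k.net_reproductive_rate(s)
            assert (r > 0) == (R0 > 1) or math.isclose(R0, 1.0, abs_tol=1e-12)

    def test_concentrated_reproduction_sets_generation_time(self):
        # with all reproduction at a single age x, T -> x
        s = make_schedule([4], [0.8], [10.0])
        R0 = k.net_reproductive_rate(s)
        r = k.intrinsic_rate(s)
        assert k.generation_time(R0, r) == pytest.approx(4.0, abs=1e-8)


class TestGenerationTime:
    @pytest.mark.parametrize(
        "R0, r, T",
        [
            (304, 0.80, 7.146),  # matches the susceptible-strain printed value
            (math.e, 1.0, 1.0),
            (302, 0.83, 6.882),  # the kdr-only strain column
        ],
    )
    def test_identity(self, R0, r, T):
        assert k.generation_time(R0, r) == pytest.approx(T, abs=5e-3)

    def test_undefined_at_zero_growth(self):
        with pytest.raises(ValidationError):
            k.generation_time(1.0, 0.0)


class TestFitnessCostRatio:
    @pytest.mark.parametrize(
        "resistant, susceptible, ratio",
        [(179, 304, 0.411), (207, 304, 0.319), (304, 304, 0.0)],
    )
    def test_values(self, resistant, susceptible, ratio):
        assert k.fitness_cost_ratio(resistant, susceptible) == pytest.approx(ratio, abs=5e-4)

    def test_rejects_zero_reference(self):
        with pytest.raises(ValidationError):
            k.fitness_cost_ratio(100, 0)


class TestAdditivityAnova:
    @staticmethod
    def frame(cell_values):
        rows = []
        for (kdr, cyp), vals in cell_values.items():
            rows += [{"kdr": kdr, "cyp": cyp, "value": v} for v in vals]
        return pd.DataFrame(rows)

    def test_additive_means_have_zero_interaction(self):
        cells = {
            (kdr, cyp): [10 + 2 * kdr + 3 * cyp] * 3 for kdr in (0, 1) for cyp in (0, 1)
        }
        table = k.additivity_anova(self.frame(cells))
        assert table.loc["kdr:cyp", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
        assert table.attrs["degenerate"]  # zero residual variance flagged

    def test_interaction_f_matches_hand_decomposition(self):
        # per-cell replicates with noise of known SS; interaction contrast
        # C = m11 - m10 - m01 + m00, SS_int = n C^2 / 4
        n = 3
        cells = {
            (0, 0): [10.0, 11.0, 12.0],
            (1, 0): [13.0, 14.0, 15.0],
            (0, 1): [16.0, 17.0, 18.0],
            (1, 1): [25.0, 26.0, 27.0],
        }
        means = {key: np.mean(v) for key, v in cells.items()}
        contrast = means[(1, 1)] - means[(1, 0)] - means[(0, 1)] + means[(0, 0)]
        ss_int = n * contrast**2 / 4
        ss_resid = sum(sum((x - np.mean(v)) ** 2 for x in v) for v in cells.values())
        mse = ss_resid / (4 * (n - 1))
        table = k.additivity_anova(self.frame(cells))
        assert table.loc["kdr:cyp", "sum_sq"] == pytest.approx(ss_int, rel=1e-9)
        assert table.loc["kdr:cyp", "F"] == pytest.approx(ss_int / mse, rel=1e-9)

    def test_unbalanced_rejected(self):
        cells = {
            (0, 0): [1.0, 2.0],
            (1, 0): [1.0, 2.0, 3.0],
            (0, 1): [1.0, 2.0],
            (1, 1): [1.0, 2.0],
        }
        with pytest.raises(DesignError, match="balanced"):
            k.additivity_anova(self.frame(cells))

    def test_empty_cell_rejected(self):
        cells = {(0, 0): [1.0, 2.0], (1, 0): [1.0, 2.0], (0, 1): [1.0, 2.0]}
        with pytest.raises(DesignError):
            k.additivity_anova(self.frame(cells))


class TestKaplanMeier:
    def test_no_deaths_flat(self):
        records = [k.DailyCohortRecord(d, 10, 0) for d in range(1, 5)]
        sf = k.kaplan_meier_survivorship(records, n0=10)
        assert (sf.survival.iloc[-1]) == 1.0

    def test_all_die_first_day(self):
        records = [k.DailyCohortRecord(1, 0, 0)]
        sf = k.kaplan_meier_survivorship(records, n0=10)
        assert sf.survival.iloc[-1] == 0.0

    def test_matches_raw_survivorship_without_censoring(self):
        vitals = k.StrainVitals(1.0, 0.5, 20)
        counts = [20, 18, 15, 15, 9, 4, 1]
        records = [k.DailyCohortRecord(d + 1, c, 0) for d, c in enumerate(counts)]
        sched = k.build_schedule(records, vitals)
        sf = k.kaplan_meier_survivorship(records, n0=20).set_index("day").survival
        for day, l in zip(sched.ages, sched.l_x):
            assert sf.loc[day] == pytest.approx(l, abs=1e-12)


@given(
    st.lists(
        st.tuples(st.floats(0.5, 1.0), st.floats(0.0, 4.0)), min_size=1, max_size=15
    )
)
@settings(max_examples=60, deadline=None)
def test_growth_rate_sign_matches_net_reproduction(pairs):
    """r > 0 iff R0 > 1, r < 0 iff R0 < 1, over random survival/fecundity schedules."""
    ages = list(range(1, len(pairs) + 1))
    surv = np.cumprod([p for p, _ in pairs])
    mx = [m for _, m in pairs]
    s = make_schedule(ages, surv, mx)
    R0 = k.net_reproductive_rate(s)
    if R0 <= 0:
        return
    r = k.intrinsic_rate(s)
    if not math.isclose(R0, 1.0, rel_tol=1e-9):
        assert (r > 0) == (R0 > 1)
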