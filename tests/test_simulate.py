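"""Synthetic-data generators: determinism, ground truth, parameter recovery."""

import numpy as np
import pytest
from scipy import stats

import kdrcost as k
from kdrcost.drift import simulate_final_freqs
from kdrcost.simulate import FOUNDER_PRESETS


def cage_allele_freqs(series):
    return [[k.allele_frequency(c).p_R for c in s] for s in series]


class TestCageSimulator:
    def test_seed_contract(self):
        cfg = k.CageSimConfig(seed=123, n_cages=2)
        s1, t1 = k.simulate_cage_experiment(cfg)
        s2, t2 = k.simulate_cage_experiment(cfg)
        assert cage_allele_freqs(s1) == cage_allele_freqs(s2)
        assert t1["allele_freq"] == t2["allele_freq"]

    def test_neutral_large_population_stays_at_half(self):
        cfg = k.CageSimConfig(N=10**6, n_cages=2, seed=5)
        series, _ = k.simulate_cage_experiment(cfg)
        for freqs in cage_allele_freqs(series):
            # founders all RS; only genotyping-sample noise remains
            assert all(abs(f - 0.5) < 5 * np.sqrt(0.25 / (2 * 90)) for f in freqs)

    def test_lethal_homozygote(self):
        cfg = k.CageSimConfig(
            N=2000, fitness=k.FitnessSpec(1.0, 1.0, 0.0), n_cages=1, seed=6
        )
        series, truth = k.simulate_cage_experiment(cfg)
        freqs = list(truth["allele_freq"]["C1"].values())
        assert freqs[-1] < freqs[0]
        # the lethal class never appears among genotyped adults of later generations
        assert all(c.n_RR == 0 for c in series[0].samples[1:])

    def test_founder_presets(self):
        series, _ = k.simulate_cage_experiment(
            k.CageSimConfig(founder=FOUNDER_PRESETS["KR-cross"], n_cages=1, seed=7)
        )
        f1 = series[0].samples[0]
        # ~7% SS contamination in the founding generation, no RR
        assert f1.n_RR == 0 and 0 < f1.n_SS < 20

    def test_round_trip_through_reader(self, tmp_path):
        series, _ = k.simulate_cage_experiment(k.CageSimConfig(seed=8, n_cages=3))
        path = tmp_path / "sim.csv"
        k.write_genotype_table(series, path, experiment="sim")
        again = k.read_genotype_table(path)
        assert cage_allele_freqs(series) == cage_allele_freqs(again)

    def test_neutral_intervals_give_uniform_drift_pvalues(self):
        # self-consistency: true frequency changes generated by the cage
        # simulator are uniform under the drift null test (the truth ledger is
        # used so that genotyping-subsample noise does not enter)
        rng = np.random.default_rng(9)
        cfg = k.DriftConfig(N=800, n_sims=2000, generations_per_interval=2)
        ps = []
        for seed in range(200):
            _, truth = k.simulate_cage_experiment(
                k.CageSimConfig(N=800, n_cages=1, seed=seed, sampled_generations=(1, 3))
            )
            freqs = truth["allele_freq"]["C1"]
            ps.append(k.drift_pvalue(freqs[1], freqs[3], cfg, rng).p)
        # the direction-selected tail is uniform on (0, 1/2]; double it
        d, _ = stats.kstest(np.minimum(1.0, 2 * np.asarray(ps)), "uniform")
        assert d < 0.1


class TestLifeTableSimulator:
    def test_determinism(self):
        cfg = k.CohortSimConfig(seed=11, replicates=2)
        r1, v1, t1 = k.simulate_life_table(cfg)
        r2, v2, t2 = k.simulate_life_table(cfg)
        assert r1 == r2 and v1 == v2 and t1["R0"] == t2["R0"]

    def test_no_mortality_closed_form(self):
        cfg = k.CohortSimConfig(
            gompertz_a=0.0, eggs_per_event=10.0, egg_viability=1.0,
            sex_ratio_female=0.5, max_days=9, replicates=1, seed=12,
        )
        # no deaths, eggs every 3rd day: analytic R0 = 3 events * 10 * 0.5
        assert cfg.true_R0() == pytest.approx(15.0)

    def test_estimates_near_truth(self):
        cfg = k.CohortSimConfig(seed=13, replicates=3)
        reps, vitals, truth = k.simulate_life_table(cfg)
        r0s = [
            k.growth_summary(records, vitals, replicate=str(i)).R0
            for i, records in enumerate(reps)
        ]
        assert np.mean(r0s) == pytest.approx(truth["R0"], rel=0.2)

    def test_schedule_recovery_from_records(self):
        # build_schedule on simulated records reproduces l_x exactly from the
        # drawn lifespans
        cfg = k.CohortSimConfig(seed=14, replicates=1)
        (records,), vitals, _ = k.simulate_life_table(cfg)
        s = k.build_schedule(records, vitals)
        assert s.l_x[0] == 1.0
        assert all(a <= b for a, b in zip(s.l_x[1:], s.l_x))


class TestMatingSimulator:
    def test_extreme_theta(self):
        trials, _ = k.simulate_mating_trials(k.MatingSimConfig(theta=0.0, seed=15))
        tally = k.tally_sires(trials)
        assert tally.n_resistant_sired == 0
        assert k.preference_test(tally).p < 1e-6

    def test_theta_recovered_and_detected(self):
        # the susceptible-female scenario: theta = 0.38, 14 replicates of 25
        rejections, props = 0, []
        for seed in range(40):
            trials, _ = k.simulate_mating_trials(
                k.MatingSimConfig(theta=0.38, seed=seed)
            )
            res = k.preference_test(k.tally_sires(trials))
            props.append(res.proportion_resistant)
            rejections += res.p < 0.05
        assert np.mean(props) == pytest.approx(0.38, abs=0.03)
        assert rejections > 30  # power is high at n = 350

    def test_error_rate_injects_inconsistencies(self):
        trials, _ = k.simulate_mating_trials(
            k.MatingSimConfig(theta=0.5, error_rate=0.3, seed=16)
        )
        assert k.tally_sires(trials).n_inconsistent > 0

    def test_determinism(self):
        cfg = k.MatingSimConfig(theta=0.4, seed=17)
        t1, _ = k.simulate_mating_trials(cfg)
        t2, _ = k.simulate_mating_trials(cfg)
        assert t1 == t2


def test_selection_coefficient_recovery():
    """A grid-search fit over s on simulated cage series recovers the truth.

    The estimator (deterministic-trajectory multinomial pseudo-likelihood) is
    a test utility, not an analysis method.
    """
    import math

    def fit_s(series, founder, grid):
        best, best_ll = None, -math.inf
        for s_val in grid:
            w = (1.0, 1.0, 1.0 - s_val)
            ll = 0.0
            for cage in series:
                props = np.array(founder, dtype=float)
                gen = 1
                for sample in cage:
                    while gen < sample.generation:
                        weighted = props * w
                        p = (weighted[2] + 0.5 * weighted[1]) / weighted.sum()
                        props = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
                        gen += 1
                    obs = np.array([sample.n_SS, sample.n_RS, sample.n_RR])
                    ll += float(np.sum(obs * np.log(np.maximum(props, 1e-12))))
            if ll > best_ll:
                best, best_ll = s_val, ll
        return best

    grid = np.arange(0.0, 0.45, 0.01)
    hits = 0
    n_runs = 30
    for seed in range(n_runs):
        series, _ = k.simulate_cage_experiment(
            k.CageSimConfig(fitness=k.FitnessSpec(1.0, 1.0, 0.8), seed=seed)
        )
        s_hat = fit_s(series, (0.0, 1.0, 0.0), grid)
        hits += abs(s_hat - 0.2) <= 0.1
    assert hits >= 0.8 * n_runs
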