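"""Langmuir basis, drift correction, and the regularized distribution fit."""

import numpy as np
import pytest

import softcorona as sc
from softcorona.errors import (
    ConfigurationError,
    EmptyDistributionError,
    InsufficientBaselineError,
)

SCHEDULE = sc.InjectionSchedule()  # 20-3000 nM, 0-800 s assoc, 2400 s end


def single_site_sensorgram(kd, koff, amp=100.0, noise=0.0, seed=0, drift=0.0):
    cfg = sc.SprSimConfig(
        true_sites=((kd, koff, amp),), noise_sigma=noise, seed=seed,
        drift_slope=drift,
    )
    return sc.generate_sensorgrams(cfg)


class TestLangmuirBasis:
    def test_half_saturation_at_kd(self):
        sched = sc.InjectionSchedule(concentrations_nM=(100.0,))
        theta = sc.langmuir_basis(100e-9, 1e-2, sched, np.array([0.0, 799.0]))
        # C = K_D and t >> 1/(ka C + koff): theta_eq = 0.5
        assert theta[0, 1] == pytest.approx(0.5, abs=1e-6)

    def test_dissociation_half_life(self):
        koff = 1e-2
        t_half = SCHEDULE.t_inject_end + np.log(2) / koff
        times = np.array([SCHEDULE.t_inject_end, t_half])
        theta = sc.langmuir_basis(1e-7, koff, SCHEDULE, times)
        assert theta[0, 1] == pytest.approx(theta[0, 0] / 2, rel=1e-9)

    def test_sequential_equals_independent_after_full_dissociation(self):
        """With complete dissociation between cycles, carrying occupancy
        across cycles reduces to per-cycle reset."""
        sched = sc.InjectionSchedule(concentrations_nM=(100.0, 100.1))
        times = np.arange(0.0, sched.t_dissoc_end, 5.0)
        fast = sc.langmuir_basis(1e-7, 1e-1, sched, times, "sequential_titration")
        indep = sc.langmuir_basis(1e-7, 1e-1, sched, times, "independent_cycles")
        np.testing.assert_allclose(fast, indep, atol=1e-12)

    def test_occupancy_bounded(self):
        times = np.arange(0.0, 2400.0, 10.0)
        for mode in ("independent_cycles", "sequential_titration"):
            theta = sc.langmuir_basis(1e-6, 1e-3, SCHEDULE, times, mode)
            assert np.all(theta >= 0) and np.all(theta <= 1)

    def test_equilibrium_limit(self):
        """Association approaches C/(C + K_D) for t >> 1/(ka C + koff)."""
        kd, koff = 1e-7, 1e-1  # ka C + koff ~ 0.4 s^-1 at 300 nM
        sched = sc.InjectionSchedule(concentrations_nM=(300.0,))
        theta = sc.langmuir_basis(kd, koff, sched, np.array([700.0]))
        assert theta[0, 0] == pytest.approx(300e-9 / (300e-9 + kd), abs=1e-6)


class TestDesignMatrix:
    def test_entries_bounded_and_distinct_columns(self):
        grid = sc.default_grid()
        times = [np.arange(0.0, 2400.0, 25.0)] * SCHEDULE.n_cycles
        a = sc.build_design_matrix(grid, SCHEDULE, times)
        assert a.min() >= 0 and a.max() <= 1
        # spot-check pairwise distinctness on a few random column pairs
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j = rng.choice(a.shape[1], 2, replace=False)
            assert np.linalg.norm(a[:, i] - a[:, j]) > 0

    def test_single_node_linearity(self):
        grid = sc.default_grid()
        times = [np.arange(0.0, 2400.0, 25.0)] * SCHEDULE.n_cycles
        a = sc.build_design_matrix(grid, SCHEDULE, times)
        weights = np.zeros(a.shape[1])
        weights[100] = 37.5
        model = a @ weights
        np.testing.assert_allclose(model, 37.5 * a[:, 100], rtol=1e-12)


class TestDriftCorrect:
    def windows(self):
        return (0.0, 0.0), (2300.0, 2400.0)

    def test_pure_drift_removed(self):
        t = np.arange(0.0, 2400.0, 10.0)
        s = sc.Sensorgram(time=t, response=0.1 * t, cycle=np.zeros(len(t)))
        out = sc.drift_correct(s, (0.0, 100.0), (2300.0, 2400.0))
        np.testing.assert_allclose(out.response, 0.0, atol=1e-9)
        assert out.drift_corrected

    def test_zero_drift_identity(self):
        # delayed injection leaves a true pre-injection baseline at t < 100 s
        sched = sc.InjectionSchedule(
            concentrations_nM=(300.0,), t_inject_start=100.0,
            assoc_window=(102.0, 798.0),
        )
        cfg = sc.SprSimConfig(true_sites=((1e-7, 1e-1, 50.0),), schedule=sched,
                              noise_sigma=0.0)
        sgram, _ = sc.generate_sensorgrams(cfg)
        out = sc.drift_correct(sgram, (0.0, 90.0), (2300.0, 2400.0))
        # koff 1e-1: response fully decayed well before 2300 s
        np.testing.assert_allclose(out.response, sgram.response, atol=1e-6)

    def test_mean_of_slopes_rule(self):
        t = np.arange(0.0, 2400.0, 10.0)
        resp = np.where(t <= 100, 0.05 * t, 0.0)
        resp = resp + np.where(t >= 2300, 0.15 * t - 0.15 * 2300 + 0.05 * 100, 0.0)
        # piecewise baseline: slope 0.05 before, 0.15 after -> mean 0.10
        s = sc.Sensorgram(time=t, response=resp, cycle=np.zeros(len(t)))
        out = sc.drift_correct(s, (0.0, 100.0), (2300.0, 2400.0))
        pre = (t >= 0) & (t <= 100)
        slope = np.polyfit(t[pre], resp[pre] - out.response[pre], 1)[0]
        assert slope == pytest.approx(0.10, abs=1e-9)

    def test_empty_window_rejected(self):
        t = np.arange(0.0, 2400.0, 10.0)
        s = sc.Sensorgram(time=t, response=0 * t, cycle=np.zeros(len(t)))
        with pytest.raises(InsufficientBaselineError):
            sc.drift_correct(s, (-50.0, -40.0), (2300.0, 2400.0))


class TestFitDistribution:
    def test_noiseless_single_node_recovery(self):
        """Truth on a grid node: nearly all mass lands in its 3x3 patch."""
        grid = sc.default_grid()
        i, j = 7, 10
        sgram, _ = single_site_sensorgram(
            grid.kd_values[i], grid.koff_values[j], noise=0.0
        )
        fit = sc.fit_distribution(sgram, SCHEDULE, alpha=0.0)
        patch = fit.weights[i - 1 : i + 2, j - 1 : j + 2].sum()
        assert patch / fit.total_signal >= 0.95
        assert fit.total_signal == pytest.approx(100.0, rel=1e-3)

    def test_noiseless_rms_residual_vanishes(self):
        grid = sc.default_grid()
        sgram, _ = single_site_sensorgram(grid.kd_values[7], grid.koff_values[10])
        fit = sc.fit_distribution(sgram, SCHEDULE, alpha=0.0)
        assert np.sqrt(fit.rss / fit.n_points) < 1e-8

    def test_zero_response_gives_zero_distribution(self):
        t = np.arange(0.0, 2400.0, 2.0)
        sgram = sc.Sensorgram(
            time=np.tile(t, 5),
            response=np.zeros(5 * len(t)),
            cycle=np.repeat(np.arange(5), len(t)),
        )
        fit = sc.fit_distribution(sgram, SCHEDULE, alpha=1.0)
        assert fit.total_signal == 0.0

    def test_rss_monotone_in_alpha(self):
        grid = sc.default_grid()
        sgram, _ = single_site_sensorgram(
            grid.kd_values[7], grid.koff_values[10], noise=1.0, seed=5
        )
        fit = sc.fit_distribution(sgram, SCHEDULE)
        alphas = fit.alpha * np.logspace(-3, 2, 8)
        rss = [
            sc.fit_distribution(sgram, SCHEDULE, alpha=a).rss for a in alphas
        ]
        assert np.all(np.diff(rss) >= -1e-6 * max(rss))

    def test_parsimony_keeps_fit_statistically_consistent(self):
        grid = sc.default_grid()
        sgram, _ = single_site_sensorgram(
            grid.kd_values[7], grid.koff_values[10], noise=1.0, seed=6
        )
        fit = sc.fit_distribution(sgram, SCHEDULE)
        assert fit.parsimony_ok
        assert fit.rss_min <= fit.rss <= fit.rss_threshold
        assert fit.alpha > 0

    def test_cycle_count_mismatch_rejected(self):
        t = np.arange(0.0, 2400.0, 2.0)
        sgram = sc.Sensorgram(time=t, response=np.zeros(len(t)),
                              cycle=np.zeros(len(t)))
        with pytest.raises(ConfigurationError):
            sc.fit_distribution(sgram, SCHEDULE)


class TestPopulationFractions:
    def delta_grid(self, i=5, j=5, w=10.0):
        grid = sc.default_grid()
        grid.weights[i, j] = w
        return grid

    def test_full_grid_region_gets_everything(self):
        grid = self.delta_grid()
        out = sc.population_fractions(grid, [((1e-9, 1e-3), (1e-5, 1.0))])
        assert out["region_0"] == pytest.approx(1.0)
        assert out["unassigned"] == 0.0

    def test_delta_lands_in_its_region(self):
        grid = self.delta_grid(i=5, j=5)
        kd5, ko5 = grid.kd_values[5], grid.koff_values[5]
        regions = [
            ((kd5 / 2, kd5 * 2), (ko5 / 2, ko5 * 2)),
            ((1e-4, 1e-3), (1e-1, 1.0)),
        ]
        out = sc.population_fractions(grid, regions)
        assert out["region_0"] == 1.0 and out["region_1"] == 0.0

    def test_overlapping_regions_rejected(self):
        grid = self.delta_grid()
        with pytest.raises(ConfigurationError):
            sc.population_fractions(
                grid, [((1e-9, 1e-3), (1e-5, 1.0)), ((1e-8, 1e-7), (1e-4, 1e-3))]
            )

    def test_empty_distribution_rejected(self):
        with pytest.raises(EmptyDistributionError):
            sc.population_fractions(sc.default_grid(), [])
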