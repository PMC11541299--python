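import numpy as np
import pytest
from scipy.stats import norm

from micsim.simulate import (
    FACTOR_LEVELS,
    DesignPoint,
    LatentState,
    build_design_grid,
    draw_latents,
    draw_q_weights,
    draw_thresholds,
    load_sample,
    perceive_and_rate,
    q_weight_sd,
    sample_seed,
    save_sample,
    simulate_sample,
    solve_mean_latent_change,
    weighted_change,
)


class TestDesignGrid:
    def test_full_grid_counts(self):
        assert len(build_design_grid(replicates=1)) == 648
        assert len(build_design_grid(replicates=5)) == 3240

    def test_marginal_balance(self):
        grid = build_design_grid(replicates=1)
        for factor, levels in FACTOR_LEVELS.items():
            values = [getattr(p, factor) for p in grid]
            for level in levels:
                assert values.count(level) == 648 // len(levels)

    def test_cells_unique(self):
        grid = build_design_grid(replicates=1)
        keys = {tuple(getattr(p, f) for f in FACTOR_LEVELS) for p in grid}
        assert len(keys) == 648

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="prop_improved"):
            DesignPoint(0.0, 1.0, 0.0, 0.3, 0.5, 0.0)

    def test_replicates_validated(self):
        with pytest.raises(ValueError):
            build_design_grid(replicates=0)


class TestSampleSeeds:
    def test_stable_under_subsetting(self):
        a = sample_seed(11, 100, 2)
        b = sample_seed(11, 100, 2)
        assert np.random.default_rng(a).random() == np.random.default_rng(b).random()

    def test_distinct_across_cells(self):
        draws = {np.random.default_rng(sample_seed(11, c, r)).random()
                 for c in range(20) for r in range(3)}
        assert len(draws) == 60


class TestMeanLatentChange:
    def test_half_is_symmetric(self):
        for sd in (0.75, 1.0, 1.25):
            assert solve_mean_latent_change(0.5, sd) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # mu = 0.5 + z_{0.8} * sqrt(1 + 0.075^2)
        expected = 0.5 + norm.ppf(0.8) * np.sqrt(1 + 0.075 ** 2)
        assert solve_mean_latent_change(0.8, 1.0) == pytest.approx(expected)
        assert solve_mean_latent_change(0.8, 1.0) == pytest.approx(1.3440, abs=2e-4)

    def test_monte_carlo_cross_check(self):
        rng = np.random.default_rng(0)
        n = 1_000_000
        mu = solve_mean_latent_change(0.2, 1.25)
        delta = rng.normal(mu, 1.25, n)
        mic = rng.normal(0.5, 0.075, n)
        assert np.mean(delta > mic) == pytest.approx(0.2, abs=3 * np.sqrt(0.16 / n))

    def test_domain(self):
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                solve_mean_latent_change(bad, 1.0)


class TestDrawLatents:
    @pytest.mark.parametrize("r", [0.0, -0.5])
    def test_correlation(self, r):
        design = DesignPoint(0.0, 1.0, r, 0.5, 0.5, 0.0)
        lat = draw_latents(design, n=2000, rng=np.random.default_rng(1))
        got = np.corrcoef(lat.theta_t1, lat.delta_theta)[0, 1]
        assert abs(got - r) < 3 / np.sqrt(2000)

    def test_moments(self):
        design = DesignPoint(1.0, 1.25, 0.0, 0.8, 0.3, 0.0)
        lat = draw_latents(design, n=20_000, rng=np.random.default_rng(2))
        n = lat.delta_theta.size
        assert lat.theta_t1.mean() == pytest.approx(1.0, abs=3 / np.sqrt(n))
        sd = lat.delta_theta.std(ddof=1)
        assert sd == pytest.approx(1.25, abs=3 * 1.25 / np.sqrt(2 * n))
        mu = solve_mean_latent_change(0.8, 1.25)
        assert lat.delta_theta.mean() == pytest.approx(mu, abs=3 * 1.25 / np.sqrt(n))

    def test_wave_identity(self):
        design = DesignPoint(0.0, 0.75, -0.5, 0.2, 0.3, 0.2)
        lat = draw_latents(design, n=100, rng=np.random.default_rng(3))
        np.testing.assert_allclose(lat.theta_t2 - lat.theta_t1, lat.delta_theta)

    def test_realized_improvement_fraction(self):
        # across many seeded samples the realized improved fraction
        # should match the design level within 3 binomial SEs almost always
        design = DesignPoint(0.0, 1.0, 0.0, 0.2, 0.5, 0.0)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            lat = draw_latents(design, n=2000, rng=rng)
            taus = draw_thresholds(2000, rng=rng)
            frac = np.mean(lat.delta_theta > taus.individual_mic)
            if abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 2000):
                hits += 1
        assert hits >= 95


class TestQWeights:
    def test_sd_rule(self):
        assert q_weight_sd(0.4) == pytest.approx(0.1)
        assert q_weight_sd(0.5) == pytest.approx(0.125)
        assert q_weight_sd(0.0) == 0.0
        assert q_weight_sd(1.0) == 0.0

    @pytest.mark.parametrize("q_mean", [0.0, 1.0])
    def test_degenerate(self, q_mean):
        w = draw_q_weights(q_mean, 100, np.random.default_rng(0))
        assert np.all(w.q == q_mean)

    @pytest.mark.parametrize("q_mean", FACTOR_LEVELS["psb_mean"])
    def test_mean_after_truncation(self, q_mean):
        w = draw_q_weights(q_mean, 200_000, np.random.default_rng(1))
        assert np.all((w.q >= 0) & (w.q <= 1))
        assert abs(w.q.mean() - q_mean) < 0.01

    def test_domain(self):
        with pytest.raises(ValueError):
            draw_q_weights(1.2, 10, np.random.default_rng(0))


class TestWeightedChange:
    def _latent(self, n=500, mean=1.0):
        rng = np.random.default_rng(4)
        t1 = rng.normal(mean, 1, n)
        d = rng.normal(0.5, 1, n)
        return LatentState(t1, t1 + d, d, theta_t1_mean=mean)

    def test_no_psb_is_exact_change(self):
        lat = self._latent()
        w = draw_q_weights(0.0, 500, np.random.default_rng(0))
        np.testing.assert_array_equal(weighted_change(lat, w), lat.delta_theta)

    def test_complete_psb_is_present_state(self):
        lat = self._latent()
        w = draw_q_weights(1.0, 500, np.random.default_rng(0))
        np.testing.assert_array_equal(weighted_change(lat, w),
                                      lat.theta_t2 - 1.0)

    def test_algebraic_identity(self):
        # q*(t2 - mean) + (1-q)*(t2 - t1) == t2 - (1-q)*t1 - q*mean
        lat = self._latent()
        w = draw_q_weights(0.4, 500, np.random.default_rng(5))
        lhs = weighted_change(lat, w)
        rhs = lat.theta_t2 - (1 - w.q) * lat.theta_t1 - w.q * 1.0
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_shape_mismatch(self):
        lat = self._latent()
        w = draw_q_weights(0.4, 10, np.random.default_rng(0))
        with pytest.raises(ValueError):
            weighted_change(lat, w)


class TestThresholds:
    def test_population_moments(self):
        taus = draw_thresholds(50_000, np.random.default_rng(6)).taus
        for k, mean in enumerate((-1.5, -0.5, 0.5, 1.5)):
            n = taus.shape[0]
            assert taus[:, k].mean() == pytest.approx(
                mean, abs=3 * 0.075 / np.sqrt(n))
            assert taus[:, k].std(ddof=1) == pytest.approx(
                0.075, abs=3 * 0.075 / np.sqrt(2 * n))

    def test_always_ordered(self):
        taus = draw_thresholds(100_000, np.random.default_rng(7)).taus
        assert np.all(np.diff(taus, axis=1) > 0)


class TestPerceiveAndRate:
    def test_realized_reliability(self):
        # averaged over 50 seeds the variance ratio hits the target
        rng = np.random.default_rng(8)
        for target in (0.3, 0.5):
            ratios = []
            for _ in range(50):
                change = rng.normal(0.5, 1.0, 2000)
                taus = draw_thresholds(2000, rng)
                perceived, _ = perceive_and_rate(change, target, taus, rng)
                ratios.append(change.var(ddof=1) / perceived.var(ddof=1))
            assert abs(np.mean(ratios) - target) < 0.02

    def test_floor_rating(self):
        taus = draw_thresholds(50, np.random.default_rng(9))
        change = -10.0 + 0.01 * np.random.default_rng(1).standard_normal(50)
        perceived, rating = perceive_and_rate(
            change, 1.0, taus, np.random.default_rng(0))
        assert np.all(perceived < -9)
        assert np.all(rating == 1)

    def test_rating_above_third_threshold(self):
        taus = draw_thresholds(50, np.random.default_rng(10))
        change = taus.taus[:, 2] + 1e-9
        # reliability 1 -> no noise added beyond the constructed change
        _, rating = perceive_and_rate(change, 1.0, taus, np.random.default_rng(0))
        assert np.all(rating == 4)

    def test_ratings_rederivable(self, baseline_sample):
        k = (baseline_sample.perceived[:, None]
             > baseline_sample.thresholds.taus).sum(axis=1)
        np.testing.assert_array_equal(k + 1, baseline_sample.transition_rating)

    def test_zero_variance_rejected(self):
        taus = draw_thresholds(10, np.random.default_rng(11))
        with pytest.raises(ValueError):
            perceive_and_rate(np.zeros(10), 0.5, taus, np.random.default_rng(0))

    def test_reliability_domain(self):
        taus = draw_thresholds(10, np.random.default_rng(12))
        with pytest.raises(ValueError):
            perceive_and_rate(np.ones(10), 0.0, taus, np.random.default_rng(0))


class TestSimulateSample:
    def test_baseline_score_envelope(self, params):
        means = []
        for seed, m in zip(range(9), [-1.0, 0.0, 1.0] * 3):
            design = DesignPoint(m, 1.0, 0.0, 0.5, 0.5, 0.0)
            s = simulate_sample(design, params, rng=seed, conversion_n=1000)
            means.append(s.sum_t1.mean())
            assert 8.0 <= s.sum_t1.mean() <= 22.0
        assert np.mean(means) == pytest.approx(15.0, abs=0.5)

    def test_true_mic_low_baseline(self, params):
        design = DesignPoint(-1.0, 1.0, 0.0, 0.5, 0.5, 0.0)
        s = simulate_sample(design, params, rng=0, conversion_n=500_000)
        assert s.true_mic_prom == pytest.approx(3.07, abs=0.09)

    def test_noiseless_classification(self, params):
        # with no PSB and perfect reliability, ratings classify
        # improvement exactly against the personal third threshold
        design = DesignPoint(0.0, 1.0, 0.0, 0.5, 0.5, 0.0)
        design = design.__class__(**{**design.as_dict(),
                                     "tr_reliability": 0.5})
        rng = np.random.default_rng(21)
        lat = draw_latents(design, 2000, rng)
        taus = draw_thresholds(2000, rng)
        _, rating = perceive_and_rate(lat.delta_theta, 1.0, taus, rng)
        np.testing.assert_array_equal(
            rating >= 4, lat.delta_theta > taus.individual_mic)

    def test_psb_machinery_inert_at_zero(self, params):
        # with q = 0 the baseline reference point cannot matter
        base = dict(delta_sd=1.0, cor_theta1_delta=0.0, prop_improved=0.5,
                    tr_reliability=0.5, psb_mean=0.0)
        rng1 = np.random.default_rng(31)
        rng2 = np.random.default_rng(31)
        lat1 = draw_latents(DesignPoint(theta1_mean=0.0, **base), 500, rng1)
        lat2 = draw_latents(DesignPoint(theta1_mean=1.0, **base), 500, rng2)
        w = draw_q_weights(0.0, 500, np.random.default_rng(0))
        np.testing.assert_allclose(weighted_change(lat1, w),
                                   weighted_change(lat2, w), atol=1e-12)

    def test_determinism(self, params, baseline_design):
        a = simulate_sample(baseline_design, params, rng=5, conversion_n=1000)
        b = simulate_sample(baseline_design, params, rng=5, conversion_n=1000)
        np.testing.assert_array_equal(a.responses_t1, b.responses_t1)
        np.testing.assert_array_equal(a.transition_rating, b.transition_rating)

    def test_roundtrip(self, params, baseline_design, tmp_path):
        s = simulate_sample(baseline_design, params, n=200, rng=5,
                            conversion_n=1000)
        path = tmp_path / "sample.csv"
        save_sample(s, path)
        loaded = load_sample(path)
        assert loaded.design == s.design
        assert loaded.true_mic_prom == pytest.approx(s.true_mic_prom, rel=1e-10)
        np.testing.assert_array_equal(loaded.responses_t1, s.responses_t1)
        np.testing.assert_array_equal(loaded.responses_t2, s.responses_t2)
        np.testing.assert_array_equal(loaded.transition_rating,
                                      s.transition_rating)
        np.testing.assert_allclose(loaded.q.q, s.q.q, atol=1e-10)
        np.testing.assert_allclose(loaded.thresholds.taus, s.thresholds.taus,
                                   atol=1e-10)


class TestReferencePointModes:
    def test_sample_mean_mode(self, params, baseline_design):
        s = simulate_sample(baseline_design, params, n=300, rng=8,
                            conversion_n=1000, reference_mean="sample")
        assert s.latent.theta_t1_mean == pytest.approx(
            s.latent.theta_t1.mean())

    def test_modes_agree_at_zero_psb(self, params, baseline_design):
        # with q = 0 the reference point is inert, so both modes match
        a = simulate_sample(baseline_design, params, n=300, rng=8,
                            conversion_n=1000, reference_mean="population")
        b = simulate_sample(baseline_design, params, n=300, rng=8,
                            conversion_n=1000, reference_mean="sample")
        np.testing.assert_allclose(a.weighted, b.weighted)

    def test_invalid_mode(self, params, baseline_design):
        with pytest.raises(ValueError):
            simulate_sample(baseline_design, params, n=100, rng=0,
                            reference_mean="midpoint")
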