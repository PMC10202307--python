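"""Benchmark problem definitions: dimensions, noise conventions, simulators."""

import numpy as np
import pytest
from scipy import stats

from abcsens import model_zoo as mz


@pytest.mark.parametrize(
    "name,n_theta,n_y",
    [
        ("T1", 2, 10),
        ("T2", 1, 2),
        ("T3", 4, 7),
        ("T4", 3, 32),
        ("T5", 4, 100),
        ("T6", 3, 200),
        ("demo", 4, 17),
        ("quadratic", 1, 1),
    ],
)
def test_registered_problem_dimensions(name, n_theta, n_y):
    prob = mz.make_observed(name, seed=5)
    assert prob.n_theta == n_theta
    assert prob.n_y == n_y
    assert prob.observed.shape == (n_y,)
    y = prob.simulator(prob.prior.sample(np.random.default_rng(0)), np.random.default_rng(1))
    assert np.asarray(y).shape == (n_y,)


def test_demo_zero_noise_limit():
    y = mz.simulate_demo(np.array([1.0, 2.0, 3.0, 0.5]), np.random.default_rng(0), noise_scale=0.0)
    expected = np.array([1, 2, 3, 3, 3, 3, 0.25] + [0.0] * 10)
    np.testing.assert_allclose(y, expected)


def test_demo_wrong_dimension_raises():
    with pytest.raises(ValueError):
        mz.simulate_demo(np.zeros(3), np.random.default_rng(0))


def test_demo_y4_monte_carlo_mean():
    # y4 ~ N(theta4^2, 0.1^2): sample mean at theta4 = 0.5 approaches 0.25
    rng = np.random.default_rng(42)
    theta = np.array([0.0, 0.0, 0.0, 0.5])
    n = 100_000
    draws = np.array([mz.simulate_demo(theta, rng)[6] for _ in range(n)])
    se = 0.1 / np.sqrt(n)
    assert abs(draws.mean() - 0.25) < 3 * se


def test_quadratic_sign_symmetry_zero_noise():
    rng = np.random.default_rng(0)
    assert mz.simulate_quadratic(np.array([0.5]), rng, noise_scale=0.0)[0] == pytest.approx(0.25)
    assert mz.simulate_quadratic(np.array([-0.5]), rng, noise_scale=0.0)[0] == pytest.approx(0.25)


def test_quadratic_registered_observation():
    assert mz.make_observed("quadratic").observed[0] == pytest.approx(0.7)


def test_t2_zero_noise_and_variance():
    y = mz.simulate_t2(np.array([3.0]), np.random.default_rng(0), noise_scale=0.0)
    np.testing.assert_allclose(y, [3.0, 0.0])
    rng = np.random.default_rng(1)
    n = 100_000
    y2 = np.array([mz.simulate_t2(np.array([0.0]), rng)[1] for _ in range(n)])
    # sample variance of N(0,1); SE of the variance is ~ sqrt(2/n)
    assert abs(y2.var() - 1.0) < 3 * np.sqrt(2.0 / n)


class TestGKQuantile:
    def test_median_is_location(self):
        assert mz.gk_quantile(0.5, 3.0, 1.0, 2.7, 0.4) == pytest.approx(3.0)

    def test_normal_limit_formula(self):
        for p in (0.1, 0.25, 0.9):
            z = stats.norm.ppf(p)
            assert mz.gk_quantile(p, 3.0, 2.0, 0.0, 0.0) == pytest.approx(3.0 + 2.0 * z)

    def test_skew_kurtosis_value(self):
        # direct evaluation at z = 1: A + B*(1 + 0.8*tanh(g/2))*2^k
        p = stats.norm.cdf(1.0)
        assert mz.gk_quantile(p, 3.0, 1.0, 2.0, 0.5) == pytest.approx(5.275859, abs=1e-5)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mz.gk_quantile(0.0, 3.0, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            mz.gk_quantile(0.5, 3.0, -1.0, 0.0, 0.0)

    def test_normal_limit_distribution(self):
        # g = k = 0 reduces to N(A, B^2): Kolmogorov-Smirnov at n = 1e4
        rng = np.random.default_rng(3)
        x = mz.simulate_gk_order_stats(np.array([3.0, 1.0, 0.0, 0.0]), 10_000, 10_000, rng)
        assert stats.kstest(x, "norm", args=(3.0, 1.0)).pvalue > 0.01


class TestGKOrderStats:
    def test_t5_shape_and_order(self):
        rng = np.random.default_rng(0)
        x = mz.simulate_gk_order_stats(np.array([3.0, 1.0, 2.0, 0.5]), 10_000, 100, rng)
        assert x.shape == (100,)
        assert np.all(np.diff(x) >= 0)

    def test_median_statistic_location(self):
        rng = np.random.default_rng(1)
        theta = np.array([3.0, 1.0, 0.0, 0.0])
        meds = [mz.simulate_gk_order_stats(theta, 1000, 7, rng)[3] for _ in range(200)]
        assert abs(np.mean(meds) - 3.0) < 0.05

    def test_invalid_counts(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            mz.simulate_gk_order_stats(np.zeros(4) + 1.0, 0, 1, rng)
        with pytest.raises(ValueError):
            mz.simulate_gk_order_stats(np.zeros(4) + 1.0, 10, 11, rng)


class TestGillespie:
    def test_zero_rates_frozen(self):
        rng = np.random.default_rng(0)
        out = mz.gillespie_lv(np.zeros(3), (50, 100), np.linspace(0, 20, 5), rng)
        np.testing.assert_allclose(out, [50] * 5 + [100] * 5)

    def test_pure_death_expectation(self):
        # only predator death at rate 0.3: E[Y(1)] = 100 * exp(-0.3)
        rng = np.random.default_rng(7)
        n = 10_000
        counts = np.array(
            [mz.gillespie_lv(np.array([0.0, 0.0, 0.3]), (0, 100), np.array([1.0]), rng)[1] for _ in range(n)]
        )
        target = 100 * np.exp(-0.3)
        se = counts.std() / np.sqrt(n)
        assert abs(counts.mean() - target) < 3 * se

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            mz.gillespie_lv(np.array([-0.1, 0.0, 0.0]), (1, 1), np.array([1.0]), np.random.default_rng(0))

    def test_event_cap_sentinel(self):
        # explosive prey growth hits the cap -> all-inf sentinel, no exception
        rng = np.random.default_rng(0)
        out = mz.gillespie_lv(np.array([5.0, 0.0, 0.0]), (50, 0), np.array([20.0]), rng, max_events=100)
        assert np.all(np.isinf(out))


class TestConversionReaction:
    def test_closed_form_one_way(self):
        y = mz.simulate_conversion(np.array([0.2, 1e-12]), np.random.default_rng(0), noise_scale=0.0)
        t = np.linspace(3.0, 30.0, 10)
        np.testing.assert_allclose(y, 1.0 - np.exp(-0.2 * t), rtol=1e-6)

    def test_closed_form_symmetric_rates(self):
        y = mz.simulate_conversion(np.array([0.1, 0.1]), np.random.default_rng(0), noise_scale=0.0)
        t = np.linspace(3.0, 30.0, 10)
        np.testing.assert_allclose(y, 0.5 * (1.0 - np.exp(-0.2 * t)), rtol=1e-10)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            mz.simulate_conversion(np.array([0.0, 0.1]), np.random.default_rng(0))


class TestMakeObserved:
    def test_demo_fixed_observation(self):
        obs = mz.make_observed("demo").observed
        expected = np.zeros(17)
        expected[6] = 0.7
        np.testing.assert_allclose(obs, expected)

    def test_deterministic_under_seed(self):
        a = mz.make_observed("T5", seed=11).observed
        b = mz.make_observed("T5", seed=11).observed
        np.testing.assert_array_equal(a, b)

    def test_t6_counts(self):
        prob = mz.make_observed("T6", seed=3)
        assert prob.observed.shape == (200,)
        assert np.all(prob.observed >= 0)
        assert np.all(prob.observed == np.round(prob.observed))
        np.testing.assert_allclose(prob.ground_truth, [0.5, 0.0025, 0.3])

    def test_unknown_problem(self):
        with pytest.raises(KeyError):
            mz.make_observed("no-such-problem")

    def test_truth_outside_prior_rejected(self):
        with pytest.raises(ValueError):
            mz.make_observed("T5", theta_true=np.array([11.0, 1.0, 1.0, 1.0]))

    def test_observed_csv_export(self, tmp_path):
        import pandas as pd

        prob = mz.make_observed("T2", seed=4)
        path = tmp_path / "obs.csv"
        prob.to_csv(path)
        df = pd.read_csv(path)
        assert len(df) == 1
        np.testing.assert_allclose(df[["y_1", "y_2"]].to_numpy()[0], prob.observed)
        assert df["theta_1"][0] == pytest.approx(prob.ground_truth[0])


class TestPriorSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            mz.PriorSpec((("uniform", 1.0, 0.0),))
        with pytest.raises(ValueError):
            mz.PriorSpec((("normal", 0.0, 0.0),))

    def test_uniform_sample_density_consistency(self):
        prior = mz.PriorSpec((("uniform", -7.0, 7.0), ("normal", 1.0, 4.0)))
        rng = np.random.default_rng(0)
        draws = prior.sample(rng, 20_000)
        assert abs(draws[:, 0].mean() - 0.0) < 3 * 14 / np.sqrt(12 * 20_000)
        assert abs(draws[:, 1].mean() - 1.0) < 3 * 2 / np.sqrt(20_000)
        assert all(prior.pdf(th) > 0 for th in draws[:100])
        assert prior.pdf(np.array([8.0, 0.0])) == 0.0
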