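"""ABC-SMC engine: calibration, proposals, thresholds, full runs."""

import numpy as np
import pytest
from scipy import integrate

from abcsens import model_zoo as mz
from abcsens import smc


class TestNextEpsilon:
    def test_median_conventions(self):
        assert smc.next_epsilon([1.0, 2.0, 3.0]) == 2.0
        assert smc.next_epsilon([1.0, 2.0, 3.0, 4.0]) == 2.5
        assert smc.next_epsilon([5.0, 5.0, 5.0]) == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            smc.next_epsilon([])


class TestCalibrate:
    def test_epsilon_is_median_of_own_distances(self):
        prob = mz.make_observed("quadratic")
        gen, n_sims = smc.calibrate(prob, 64, np.random.default_rng(0))
        assert n_sims == 64
        assert gen.eps_next == pytest.approx(np.median(gen.distances))
        np.testing.assert_allclose(gen.weights, np.full(64, 1 / 64))
        assert gen.thetas.shape == (64, 1)

    def test_deterministic_under_seed(self):
        prob = mz.make_observed("quadratic")
        g1, _ = smc.calibrate(prob, 32, np.random.default_rng(9))
        g2, _ = smc.calibrate(prob, 32, np.random.default_rng(9))
        np.testing.assert_array_equal(g1.data, g2.data)
        assert g1.eps_next == g2.eps_next


class TestProposal:
    def test_identical_particles_jitter_only(self):
        th = np.ones((5, 2))
        prop = smc.build_proposal(th, np.full(5, 0.2))
        assert np.all(np.diag(prop.cov) > 0)
        assert np.all(np.diag(prop.cov) < 1e-8)

    def test_two_particle_covariance(self):
        # weighted variance of {0, 2} at equal weight is 1; doubled -> 2
        prop = smc.build_proposal(np.array([[0.0], [2.0]]), np.array([0.5, 0.5]))
        assert prop.cov[0, 0] == pytest.approx(2.0)

    def test_mixture_density_normalized(self):
        rng = np.random.default_rng(0)
        th = rng.normal(size=(6, 1))
        w = rng.uniform(0.1, 1.0, size=6)
        prop = smc.build_proposal(th, w)
        total, _ = integrate.quad(lambda x: prop.pdf(np.array([x])), -30, 30)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_local_mixture_density_normalized(self):
        rng = np.random.default_rng(1)
        th = rng.normal(size=(8, 1))
        w = rng.uniform(0.1, 1.0, size=8)
        d = rng.uniform(0.0, 1.0, size=8)
        prop = smc.build_local_proposal(th, w, d, 0.6)
        total, _ = integrate.quad(lambda x: prop.pdf(np.array([x])), -30, 30)
        assert total == pytest.approx(1.0, abs=1e-6)
        assert all(prop.pdf(c) > 0 for c in prop.centers)

    def test_degenerate_weight_rejected(self):
        with pytest.raises(ValueError):
            smc.build_proposal(np.zeros((3, 1)), np.zeros(3))


class TestProposeAndWeight:
    def test_prior_generation_unit_weight(self):
        prior = mz.PriorSpec((("uniform", -1.0, 1.0),))
        theta, w = smc.propose_and_weight(None, prior, np.random.default_rng(0))
        assert w == 1.0
        assert prior.in_support(theta)

    def test_support_rejection(self):
        prior = mz.PriorSpec((("uniform", 0.0, 1.0),))
        # kernel straddling the support boundary: only in-support draws return
        prop = smc.build_proposal(np.array([[-0.4], [0.4]]), np.array([0.5, 0.5]))
        rng = np.random.default_rng(0)
        for _ in range(50):
            theta, w = smc.propose_and_weight(prop, prior, rng)
            assert 0.0 <= theta[0] <= 1.0
            assert w > 0

    def test_importance_identity(self):
        # E_g[pi/g] = 1 for a proper prior whose mass the proposal covers
        prior = mz.PriorSpec((("normal", 0.0, 1.0),))
        prop = smc.build_proposal(
            np.random.default_rng(1).normal(0, 2, size=(100, 1)), np.full(100, 0.01)
        )
        rng = np.random.default_rng(2)
        ws = np.array([smc.propose_and_weight(prop, prior, rng)[1] for _ in range(4000)])
        assert ws.mean() == pytest.approx(1.0, abs=0.1)


@pytest.fixture(scope="module")
def gauss_result():
    cfg = smc.RunConfig(problem="gauss1d", n_particles=400, budget=15_000, seed=1, max_generations=10)
    return smc.run(cfg)


class TestRun:
    def test_conjugate_posterior_recovery(self, gauss_result):
        # prior N(0,1), y ~ N(theta,1), y_obs = 1 -> posterior N(0.5, 0.5)
        th, w = gauss_result.posterior_sample
        mean = w @ th[:, 0]
        var = w @ (th[:, 0] - mean) ** 2
        assert mean == pytest.approx(0.5, abs=0.05)
        assert var == pytest.approx(0.5, abs=0.1)

    def test_importance_weights_normalized(self, gauss_result):
        for gen in gauss_result.generations:
            assert gen.weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(gen.distances[gen.accepted] <= gen.epsilon)

    def test_budget_accounting_exact(self, gauss_result):
        per_gen = sum(g.n_simulations for g in gauss_result.generations)
        assert per_gen == gauss_result.total_simulations
        assert gauss_result.total_simulations <= gauss_result.config.budget

    def test_epsilon_decreases(self, gauss_result):
        eps = [g.epsilon for g in gauss_result.generations[1:]]
        assert eps[-1] < eps[0]

    def test_bit_reproducible(self):
        cfg = smc.RunConfig(problem="quadratic", n_particles=100, budget=1500, seed=3, max_generations=4)
        r1, r2 = smc.run(cfg), smc.run(cfg)
        np.testing.assert_array_equal(r1.final_generation.thetas, r2.final_generation.thetas)
        np.testing.assert_array_equal(r1.final_generation.weights, r2.final_generation.weights)
        assert r1.epsilon_trajectory == r2.epsilon_trajectory

    def test_global_kernel_option(self):
        cfg = smc.RunConfig(
            problem="gauss1d", n_particles=100, budget=2000, seed=2, max_generations=4,
            proposal_kind="global",
        )
        res = smc.run(cfg)
        th, w = res.posterior_sample
        assert abs(w @ th[:, 0] - 0.5) < 0.3

    def test_partial_generation_flagged(self):
        cfg = smc.RunConfig(problem="gauss1d", n_particles=200, budget=450, seed=0, max_generations=10)
        res = smc.run(cfg)
        assert res.total_simulations <= 450
        if any(g.partial for g in res.generations):
            assert res.generations[-1].partial
            assert not res.final_generation.partial or len(res.generations) == 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            smc.RunConfig(problem="gauss1d", n_particles=1)
        with pytest.raises(ValueError):
            smc.RunConfig(problem="gauss1d", n_particles=100, budget=50)


class TestStatisticsModeEndToEnd:
    def test_statistics_switch_trains_and_compares_summaries(self):
        from abcsens.regression import RegressionSpec

        cfg = smc.RunConfig(
            problem="gauss1d",
            n_particles=150,
            budget=4000,
            regression=RegressionSpec(family="linear", k=1, train_fraction=0.3, mode="statistics"),
            seed=4,
            max_generations=8,
        )
        res = smc.run(cfg)
        assert res.regressor is not None
        # after the switch the distance operates on 1-d summaries
        assert res.generations[-1].distance_state.sigma.size == res.regressor.n_lambda
        th, w = res.posterior_sample
        assert abs(w @ th[:, 0] - 0.5) < 0.15
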