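"""Resource-gain parametrization, costs, expected loss, and optimization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rinatt import (
    CONTRAST_LEVELS,
    ContrastResponse,
    CostModel,
    ObserverParams,
    OrientationPrior,
    ResourceGain,
    average_precision,
    expected_loss,
    expected_reward,
    mutual_information_cost,
    optimize,
    parametrize_g,
    reward_environment,
)
from rinatt.resource import InvalidCoefficientsError, StimulusPairSet, objective
from rinatt.stimulus import doubled


def _observer(gain=None, k_max=20.0, sigma_late=8.0):
    return ObserverParams(
        gain=gain or ResourceGain.uniform(),
        cr=ContrastResponse(k_max=k_max, q=2.0, c50=0.4),
        sigma_late=sigma_late,
    )


class TestParametrizeG:
    def test_zero_coefficients_give_uniform_gain(self):
        g = parametrize_g((0.0, 0.0, 0.0))
        np.testing.assert_allclose(g.values, 1.0)

    @given(
        g0=st.floats(-1.5, 1.5), g1=st.floats(-1.5, 1.5), g2=st.floats(-1.5, 1.5)
    )
    @settings(max_examples=60, deadline=None)
    def test_unit_mean_for_any_valid_coefficients(self, g0, g1, g2):
        try:
            g = parametrize_g((g0, g1, g2))
        except InvalidCoefficientsError:
            return
        assert g.values.mean() == pytest.approx(1.0, abs=1e-9)
        assert (g.values > 0).all()
        # mirrored construction: symmetric about the vertical meridian
        np.testing.assert_allclose(g.values, g.values[::-1])

    def test_matches_finite_difference_of_antiderivative(self):
        g0, g1, g2 = 0.5, 0.0, 0.0
        g = parametrize_g((g0, g1, g2))

        def big_g(x):
            return x * (1.0 + (x - 1.0) * (g0 + g1 * x + g2 * x**2))

        half = g.grid.size // 2
        x = (np.arange(half) + 0.5) / half
        h = 1e-6
        oracle = (big_g(x + h) - big_g(x - h)) / (2 * h)
        oracle = np.concatenate([oracle, oracle[::-1]])
        np.testing.assert_allclose(g.values, oracle / oracle.mean(), rtol=1e-6)

    def test_non_monotone_antiderivative_rejected(self):
        with pytest.raises(InvalidCoefficientsError):
            parametrize_g((4.0, 0.0, 0.0))


class TestCosts:
    def test_average_precision_separable_case(self, prior):
        params = _observer()
        k_bar = average_precision(params, prior, contrasts=(0.6,))
        # uniform g: k_bar = k(c) * sum(pi * 1)
        assert k_bar == pytest.approx(params.cr.k(0.6))

    def test_average_precision_rises_with_gain_at_prior_peak(self, prior):
        horizontal_heavy = parametrize_g((-0.8, 0.0, 0.0))  # more gain at x=0
        assert horizontal_heavy.values[0] > 1.0
        assert average_precision(_observer(horizontal_heavy), prior) > average_precision(
            _observer(), prior
        )

    def test_average_precision_three_contrast_oracle(self, prior):
        params = _observer(parametrize_g((0.8, -0.3, 0.1)))
        total = 0.0
        for c in CONTRAST_LEVELS:
            total += float(np.sum(prior.density * params.gain.values * params.cr.k(c)))
        assert average_precision(params, prior) == pytest.approx(total / 3.0)

    def test_mutual_information_zero_at_zero_precision(self, prior):
        params = _observer(k_max=1e-9)
        assert mutual_information_cost(params, prior) == pytest.approx(0.0, abs=1e-6)

    def test_mutual_information_increases_with_k_max(self, prior):
        mis = [
            mutual_information_cost(_observer(k_max=k), prior, contrasts=(1.0,))
            for k in (2.0, 10.0, 50.0)
        ]
        assert mis[0] < mis[1] < mis[2]

    def test_mutual_information_against_joint_entropy_oracle(self):
        # tiny 6-point grid, I = H(theta) + H(m) - H(theta, m) computed
        # directly from the joint distribution
        prior = OrientationPrior.horizontal_biased(step=30.0)
        params = ObserverParams(
            gain=ResourceGain.uniform(step=30.0),
            cr=ContrastResponse(k_max=6.0, q=2.0, c50=0.5),
            sigma_late=5.0,
        )
        c = 1.0
        conc = params.cr.k(c) * params.gain.values
        psi = doubled(prior.grid)
        pm = np.exp(conc[:, None] * (np.cos(psi[:, None] - psi[None, :]) - 1.0))
        pm /= pm.sum(axis=1, keepdims=True)
        joint = prior.density[:, None] * pm

        def entropy(p):
            p = p[p > 0]
            return float(-(p * np.log(p)).sum())

        oracle = entropy(prior.density) + entropy(joint.sum(axis=0)) - entropy(joint.ravel())
        assert mutual_information_cost(params, prior, contrasts=(c,)) == pytest.approx(oracle, rel=1e-9)


class TestExpectedLoss:
    def test_perfect_observer_loses_nothing(self, prior):
        params = _observer(k_max=5e4, sigma_late=0.0)
        env = reward_environment("constant")
        assert expected_loss(env, params, prior) < 0.05

    def test_blind_observer_loses_half_the_weighted_mass(self, prior):
        # P(error) = 0.5 everywhere, so loss = half the reward-weighted mass
        params = _observer(k_max=1e-9, sigma_late=1e6)
        for env_id in ("constant", "increasing", "decreasing"):
            env = reward_environment(env_id)
            loss = expected_loss(env, params, prior)
            reward = expected_reward(env, params, prior)
            assert loss == pytest.approx(reward, rel=1e-6)  # half each
            if env_id == "constant":
                assert loss == pytest.approx(2.5, rel=1e-6)

    def test_monte_carlo_reward_accounting(self, prior, rng):
        # sample trials from the pair distribution and simulate rewards
        from rinatt import simulate_choices
        import pandas as pd

        params = _observer(k_max=20.0, sigma_late=8.0)
        env = reward_environment("increasing")
        pairs = StimulusPairSet.from_prior(prior)
        n = 200000
        pick = rng.choice(pairs.weights.size, size=n, p=pairs.weights)
        trials = pd.DataFrame(
            {
                "theta_l": prior.grid[pairs.il[pick]],
                "theta_r": prior.grid[pairs.ir[pick]],
                "c_l": rng.choice(np.array(CONTRAST_LEVELS), size=n),
                "c_r": rng.choice(np.array(CONTRAST_LEVELS), size=n),
            }
        )
        choices = simulate_choices(trials, params, prior, rng)
        from rinatt import verticality

        v_l = verticality(trials["theta_l"].to_numpy())
        v_r = verticality(trials["theta_r"].to_numpy())
        correct = np.where(choices == "left", v_l > v_r, v_r > v_l)
        chosen = np.where(choices == "left", trials["theta_l"], trials["theta_r"])
        emp = np.where(correct, np.asarray(env.reward_for(chosen)), 0.0).mean()
        # analytic expectation within MC error plus the documented
        # Gaussian-approximation allowance on choice probabilities
        assert expected_reward(env, params, prior) == pytest.approx(emp, abs=0.08)


@pytest.fixture(scope="module")
def small_opt(prior):
    return optimize(
        reward_environment("increasing"),
        CostModel(eta=0.15),
        10.0,
        prior,
        starts=4,
        seed=3,
        cr_template=ContrastResponse(k_max=30.0, q=2.0, c50=0.4),
        maxiter=300,
    )


class TestOptimization:
    def test_objective_decomposition_exact(self, prior):
        params = _observer(parametrize_g((0.5, -0.2, 0.0)))
        env = reward_environment("increasing")
        cost = CostModel(eta=0.1)
        total = objective(env, cost, params, prior)
        parts = expected_loss(env, params, prior) + 0.1 * average_precision(params, prior)
        assert total == pytest.approx(parts, abs=1e-8)

    def test_beats_uniform_allocation(self, prior, small_opt):
        env = reward_environment("increasing")
        cost = CostModel(eta=0.15)
        uniform = ObserverParams(
            gain=ResourceGain.uniform(),
            cr=ContrastResponse(k_max=small_opt.k_max, q=2.0, c50=0.4),
            sigma_late=10.0,
        )
        assert small_opt.objective <= objective(env, cost, uniform, prior) + 1e-9

    def test_result_decomposition(self, small_opt):
        assert small_opt.objective == pytest.approx(
            small_opt.expected_loss + small_opt.cost, abs=1e-8
        )

    def test_reproducible_under_fixed_seed(self, prior, small_opt):
        again = optimize(
            reward_environment("increasing"),
            CostModel(eta=0.15),
            10.0,
            prior,
            starts=4,
            seed=3,
            cr_template=ContrastResponse(k_max=30.0, q=2.0, c50=0.4),
            maxiter=300,
        )
        assert again.objective == pytest.approx(small_opt.objective, abs=1e-12)
        np.testing.assert_allclose(again.gain.values, small_opt.gain.values)

    def test_higher_precision_cost_lowers_invested_precision(self, prior):
        env = reward_environment("constant")
        cr = ContrastResponse(k_max=30.0, q=2.0, c50=0.4)
        cheap = optimize(env, CostModel(eta=0.02), 8.0, prior, starts=4, seed=9, cr_template=cr, maxiter=300)
        dear = optimize(env, CostModel(eta=0.6), 8.0, prior, starts=4, seed=9, cr_template=cr, maxiter=300)
        k_cheap = average_precision(_observer(cheap.gain, k_max=cheap.k_max), prior)
        k_dear = average_precision(_observer(dear.gain, k_max=dear.k_max), prior)
        assert k_dear < k_cheap
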