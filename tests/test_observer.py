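"""Bayesian observer: encoding, BLS decoding, moments, and the choice rule."""

import numpy as np
import pandas as pd
import pytest

from rinatt import (
    ContrastResponse,
    ObserverParams,
    OrientationPrior,
    ResourceGain,
    bls_estimate,
    choice_probabilities,
    choice_probability,
    error_probability,
    estimator_moments,
    measurement_density,
    simulate_choices,
    verticality,
)
from rinatt.observer import decoder_table
from rinatt.stimulus import doubled


def _observer(k_max=16.0, sigma_late=5.0, **kw):
    return ObserverParams(
        gain=ResourceGain.uniform(),
        cr=ContrastResponse(k_max=k_max, q=2.0, c50=0.5),
        sigma_late=sigma_late,
        **kw,
    )


class TestMeasurementDensity:
    def test_normalized(self, prior):
        d = measurement_density(30.0, 0.6, _observer(), prior)
        assert d.sum() == pytest.approx(1.0)

    def test_zero_concentration_is_uniform(self, prior):
        params = _observer(k_max=1e-12)
        d = measurement_density(30.0, 0.6, params, prior)
        np.testing.assert_allclose(d, 1.0 / d.size, rtol=1e-6)

    def test_von_mises_mass_ratio(self, prior):
        # mass ratio between m = theta0 and a distant grid point follows the
        # closed form exp(k g (1 - cos(delta psi))) on the doubled circle
        params = _observer(k_max=16.0)  # k(0.5) = 8, uniform gain
        theta0, m_far = 44.0, 88.0
        d = measurement_density(theta0, 0.5, params, prior)
        ratio = d[prior.index_of(theta0)] / d[prior.index_of(m_far)]
        expected = np.exp(8.0 * (1.0 - np.cos(doubled(m_far - theta0))))
        assert ratio == pytest.approx(expected, rel=1e-9)


class TestBLSEstimate:
    def test_flat_prior_and_gain_returns_measurement(self):
        flat = OrientationPrior.uniform()
        for m in (30.0, 88.0, 144.0):
            assert bls_estimate(m, _observer(), flat, 0.6) == pytest.approx(m, abs=1e-9)

    def test_likelihood_dominance_at_high_concentration(self, prior):
        est = bls_estimate(46.0, _observer(k_max=4000.0), prior, 1.0)
        assert est == pytest.approx(46.0, abs=0.5)

    def test_attractive_bias_toward_prior_peak(self, prior):
        # dense-grid numerical oracle: posterior mean on a 0.1-degree grid
        params = _observer(k_max=8.0)
        m = 44.0  # on the 2-degree grid
        conc = params.cr.k(0.6)  # uniform gain
        fine = np.arange(0.0, 180.0, 0.1)
        lik = np.exp(conc * np.cos(doubled(fine) - doubled(m)))
        pri = np.exp(prior.concentration * np.cos(doubled(fine)))
        post = lik * pri / np.sum(lik * pri)
        a, b = post @ np.sin(doubled(fine)), post @ np.cos(doubled(fine))
        oracle = np.mod(np.degrees(np.arctan2(a, b)) / 2.0, 180.0)
        est = bls_estimate(m, params, prior, 0.6)
        assert est == pytest.approx(oracle, abs=0.5)
        assert est < m  # pulled toward horizontal (0 deg)


class TestEstimatorMoments:
    def test_high_precision_variance_vanishes(self, prior):
        mom = estimator_moments(40.0, 1.0, _observer(k_max=5e4, sigma_late=0.0), prior)
        assert mom.var < 0.5
        assert mom.mean == pytest.approx(verticality(40.0), abs=0.5)

    def test_flat_prior_and_gain_is_unbiased(self):
        flat = OrientationPrior.uniform()
        for theta0 in (30.0, 60.0, 120.0):
            mom = estimator_moments(theta0, 1.0, _observer(k_max=60.0), flat)
            assert mom.mean == pytest.approx(verticality(theta0), abs=1.0)

    def test_against_monte_carlo_oracle(self, prior, rng):
        # brute-force MC: sample m from the discrete measurement distribution,
        # decode with the same table, fold, and compare moments within 3 SE
        params = _observer(k_max=20.0)
        theta0, c, n = 30.0, 0.6, 10**6
        conc = params.cr.k(c) * params.gain.at(theta0)
        pm = np.exp(conc * (np.cos(doubled(prior.grid) - doubled(theta0)) - 1.0))
        pm /= pm.sum()
        idx = rng.choice(prior.grid.size, size=n, p=pm)
        v_hat = verticality(decoder_table(params, prior, c)[idx])
        mom = estimator_moments(theta0, c, params, prior)
        se_mean = v_hat.std() / np.sqrt(n)
        assert abs(mom.mean - v_hat.mean()) < 3 * se_mean
        se_var = v_hat.var() * np.sqrt(2.0 / n)
        assert abs(mom.var - v_hat.var()) < 3 * se_var

    def test_circular_convention_close_to_default_at_high_precision(self, prior):
        params = _observer(k_max=200.0)
        m_v = estimator_moments(30.0, 1.0, params, prior, convention="verticality")
        m_c = estimator_moments(30.0, 1.0, params, prior, convention="circular")
        assert m_v.mean == pytest.approx(m_c.mean, abs=1.0)


class TestChoiceRule:
    def _trial(self, **kw):
        base = dict(theta_l=40.0, theta_r=40.0, c_l=0.6, c_r=0.6, prev_choice="none")
        base.update(kw)
        return base

    def test_identical_stimuli_are_chance(self, prior):
        assert choice_probability(self._trial(), _observer(), prior) == pytest.approx(0.5)

    def test_large_side_bias_dominates(self, prior):
        p = choice_probability(self._trial(), _observer(beta0=20.0), prior)
        assert p > 0.999

    def test_bias_free_equivariance_under_side_swap(self, prior, mouse_observer):
        trials = pd.DataFrame(
            {
                "theta_l": [20.0, 30.0, 80.0, 150.0, 90.0],
                "theta_r": [60.0, 90.0, 20.0, 110.0, 40.0],
                "c_l": [0.3, 1.0, 0.6, 0.3, 1.0],
                "c_r": [1.0, 0.6, 0.3, 0.3, 0.3],
            }
        )
        swapped = trials.rename(
            columns={"theta_l": "theta_r", "theta_r": "theta_l", "c_l": "c_r", "c_r": "c_l"}
        )
        p = choice_probabilities(trials, mouse_observer, prior)
        q = choice_probabilities(swapped, mouse_observer, prior)
        np.testing.assert_allclose(p, 1.0 - q, atol=1e-12)

    def test_against_simulated_choice_frequency(self, prior, rng):
        params = _observer(k_max=20.0, sigma_late=8.0, beta0=0.3, beta2=0.5)
        trial = self._trial(theta_l=50.0, theta_r=80.0, c_l=1.0, c_r=0.3)
        p = choice_probability(trial, params, prior)
        n = 10**5
        trials = pd.DataFrame([trial] * n)
        emp = (simulate_choices(trials, params, prior, rng) == "left").mean()
        se = np.sqrt(p * (1 - p) / n)
        # binomial 3 SE plus the documented Gaussian-approximation allowance
        assert abs(p - emp) < 3 * se + 0.02

    def test_error_probability_bounded_by_chance(self, prior, mouse_observer):
        assert error_probability(40.0, 40.0, 0.6, 0.6, mouse_observer, prior) == pytest.approx(0.5)
        p = error_probability(20.0, 80.0, 1.0, 1.0, mouse_observer, prior)
        assert 0.0 < p < 0.5

    def test_pure_late_noise_limit(self, prior):
        params = _observer(sigma_late=1e6)
        assert error_probability(20.0, 80.0, 1.0, 1.0, params, prior) == pytest.approx(0.5, abs=1e-3)


class TestSimulation:
    def test_fixed_seed_reproducible(self, prior, mouse_observer):
        trials = pd.DataFrame(
            {
                "theta_l": np.linspace(0, 178, 50),
                "theta_r": np.linspace(178, 0, 50),
                "c_l": 0.6,
                "c_r": 1.0,
            }
        )
        a = simulate_choices(trials, mouse_observer, prior, np.random.default_rng(7))
        b = simulate_choices(trials, mouse_observer, prior, np.random.default_rng(7))
        assert (a == b).all()

    def test_noiseless_observer_always_correct(self, prior, rng):
        params = _observer(k_max=5e4, sigma_late=0.0)
        trials = pd.DataFrame(
            {"theta_l": [20.0, 88.0, 130.0], "theta_r": [70.0, 40.0, 168.0], "c_l": 1.0, "c_r": 1.0}
        )
        choices = simulate_choices(trials, params, prior, rng)
        v_l = verticality(trials["theta_l"].to_numpy())
        v_r = verticality(trials["theta_r"].to_numpy())
        want = np.where(v_l > v_r, "left", "right")
        assert (choices == want).all()

    def test_gaussian_approximation_adequacy(self, prior, mouse_observer, rng):
        """Analytic probit vs mechanistic simulation within 0.02 absolute."""
        thetas = [(0.0, 20.0), (20.0, 60.0), (40.0, 90.0), (150.0, 110.0)]
        for tl, tr in thetas:
            for cl, cr in [(0.3, 1.0), (1.0, 1.0), (0.6, 0.3)]:
                trials = pd.DataFrame(
                    {"theta_l": [tl] * 30000, "theta_r": tr, "c_l": cl, "c_r": cr}
                )
                p = choice_probabilities(trials[:1], mouse_observer, prior)[0]
                emp = (simulate_choices(trials, mouse_observer, prior, rng) == "left").mean()
                assert abs(p - emp) < 0.02
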