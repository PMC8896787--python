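"""Poisson population-code implementation of the rationally inattentive observer.

A bank of independent Poisson neurons with bell-shaped (von Mises) tuning
curves encodes each grating. Preferred orientations are placed by the
inverse CDF of the stimulus prior at quantile midpoints, so their local
density is proportional to the prior; with that placement the discrete BLS
decoder reduces to a likelihood-weighted sum over preferred orientations
(the prior is absorbed by the spacing). The tuning gain is
``g(theta_n) * k(c)`` -- the same resource gain function and contrast
response as the algorithmic model, with k_max playing the role of the peak
rate r_max -- plus a base rate Delta. The network trades expected reward
against a metabolic cost of eta per expected spike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .observer import ResourceGain
from .resource import InvalidCoefficientsError, StimulusPairSet, parametrize_g
from .stimulus import (
    CONTRAST_LEVELS,
    ContrastResponse,
    OrientationPrior,
    RewardEnvironment,
    doubled,
    verticality,
)

__all__ = [
    "PopulationCode",
    "preferred_orientations",
    "tuning",
    "sample_spikes",
    "decode_bls",
    "expected_spikes",
    "network_objective",
    "optimize_network",
]


def preferred_orientations(prior: OrientationPrior, n: int) -> np.ndarray:
    """Preferred orientations at the prior's quantile midpoints (density ~ prior)."""
    if n < 2:
        raise ValueError("need at least 2 neurons")
    cdf = np.cumsum(prior.density)
    quantiles = (np.arange(n) + 0.5) / n
    idx = np.searchsorted(cdf, quantiles)
    return np.sort(prior.grid[np.clip(idx, 0, prior.grid.size - 1)])


@dataclass(frozen=True)
class PopulationCode:
    """Poisson tuning-curve bank with prior-proportional preferred orientations."""

    preferred: np.ndarray
    gain: ResourceGain
    cr: ContrastResponse
    kappa_hat: float = 4.0  # tuning concentration; ~30 deg half-width default
    delta_base: float = 0.5  # spikes/trial at rest

    def __post_init__(self) -> None:
        if self.preferred.size < 2:
            raise ValueError("need at least 2 neurons")
        if np.any(np.diff(self.preferred) < 0):
            raise ValueError("preferred orientations must be sorted")
        if self.kappa_hat <= 0 or self.delta_base < 0:
            raise ValueError("require kappa_hat > 0 and delta_base >= 0")

    @classmethod
    def build(
        cls,
        prior: OrientationPrior,
        gain: ResourceGain,
        cr: ContrastResponse | None = None,
        n: int = 30,
        kappa_hat: float = 4.0,
        delta_base: float = 0.5,
    ) -> "PopulationCode":
        return cls(
            preferred=preferred_orientations(prior, n),
            gain=gain,
            cr=cr or ContrastResponse(),
            kappa_hat=kappa_hat,
            delta_base=delta_base,
        )

    @property
    def n(self) -> int:
        return self.preferred.size


def tuning(pop: PopulationCode, theta: float | np.ndarray, c: float) -> np.ndarray:
    """Expected spike counts of every neuron for stimulus (theta, c).

    ``g(theta_n) k(c) exp(kappa_hat (cos(psi_n - psi) - 1)) + Delta``; for a
    vector theta returns shape (len(theta), n).
    """
    psi_n = doubled(pop.preferred)
    psi = np.atleast_1d(doubled(theta))
    amp = pop.gain.at(pop.preferred) * pop.cr.k(c)
    f = amp[None, :] * np.exp(pop.kappa_hat * (np.cos(psi_n[None, :] - psi[:, None]) - 1.0))
    f = f + pop.delta_base
    return f[0] if np.isscalar(theta) else f


def sample_spikes(
    pop: PopulationCode, theta: float, c: float, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Independent Poisson spike counts; shape (n,) or (size, n)."""
    f = tuning(pop, theta, c)
    if size is None:
        return rng.poisson(f)
    return rng.poisson(f[None, :], size=(size, pop.n))


def _log_likelihood_table(pop: PopulationCode, c: float) -> tuple[np.ndarray, np.ndarray]:
    """log f_m(theta_n) and f_m(theta_n) over the preferred-orientation support."""
    f = tuning(pop, pop.preferred, c)  # rows: candidate theta_n, cols: neuron m
    return np.log(f), f


def decode_bls(pop: PopulationCode, spikes: np.ndarray, c: float) -> np.ndarray:
    """Discrete BLS estimate(s) from spike-count vector(s), degrees [0, 180).

    Likelihood-weighted circular mean over the preferred-orientation support
    (prior-proportional spacing absorbs the prior term); log-sum-exp
    normalized for numerical safety.
    """
    spikes = np.atleast_2d(spikes)
    if spikes.shape[1] != pop.n:
        raise ValueError("spike vector length must equal the neuron count")
    logf, f = _log_likelihood_table(pop, c)
    # loglik[trial, n] = sum_m r_m log f_m(theta_n) - sum_m f_m(theta_n)
    loglik = spikes @ logf.T - f.sum(axis=1)[None, :]
    logz = logsumexp(loglik, axis=1, keepdims=True)
    if np.any(~np.isfinite(logz)):
        raise FloatingPointError("degenerate population likelihood")
    w = np.exp(loglik - logz)
    psi_n = doubled(pop.preferred)
    a = w @ np.sin(psi_n)
    b = w @ np.cos(psi_n)
    est = np.mod(np.degrees(np.arctan2(a, b)) / 2.0, 180.0)
    return est[0] if est.size == 1 else est


def expected_spikes(
    pop: PopulationCode,
    prior: OrientationPrior,
    contrasts=CONTRAST_LEVELS,
) -> float:
    """Mean total spikes per stimulus presentation under the prior."""
    total = 0.0
    for c in contrasts:
        f = tuning(pop, prior.grid, c)  # (T, n)
        total += float(prior.density @ f.sum(axis=1))
    return total / len(contrasts)


def network_objective(
    pop: PopulationCode,
    env: RewardEnvironment,
    sigma_late: float,
    prior: OrientationPrior,
    contrasts=CONTRAST_LEVELS,
    eta_spike: float = 0.01,
    n_trials: int = 2000,
    seed: int = 0,
) -> float:
    """E[reward] - eta * E[spikes] by closed-loop simulation of the 2AFC task.

    Stimulus pairs follow the task's difficulty-restricted pair distribution;
    both sides are encoded, decoded, folded to verticality, corrupted by
    additive late noise on the decision variable, and rewarded per the
    environment. Fixed seed makes the objective deterministic (common random
    numbers across calls).
    """
    rng = np.random.default_rng(seed)
    pairs = StimulusPairSet.from_prior(prior)
    pick = rng.choice(pairs.weights.size, size=n_trials, p=pairs.weights)
    th_l = prior.grid[pairs.il[pick]]
    th_r = prior.grid[pairs.ir[pick]]
    contrasts = np.asarray(contrasts, float)
    c_l = rng.choice(contrasts, size=n_trials)
    c_r = rng.choice(contrasts, size=n_trials)
    v_hat = {}
    for side, th, cs in (("l", th_l, c_l), ("r", th_r, c_r)):
        est = np.empty(n_trials)
        for c in np.unique(cs):
            sel = cs == c
            f = tuning(pop, th[sel], c)
            spikes = rng.poisson(f)
            est[sel] = np.atleast_1d(decode_bls(pop, spikes, c))
        v_hat[side] = verticality(est)
    d = v_hat["l"] - v_hat["r"] + rng.normal(0.0, sigma_late, size=n_trials)
    chose_l = d > 0
    v_l, v_r = verticality(th_l), verticality(th_r)
    correct = np.where(chose_l, v_l > v_r, v_r > v_l)
    r_chosen = np.asarray(env.reward_for(np.where(chose_l, th_l, th_r)))
    mean_reward = float(np.mean(np.where(correct, r_chosen, 0.0)))
    return mean_reward - eta_spike * expected_spikes(pop, prior, tuple(contrasts))


def optimize_network(
    env: RewardEnvironment,
    eta_spike: float,
    sigma_late: float,
    prior: OrientationPrior,
    contrasts=CONTRAST_LEVELS,
    starts: int = 8,
    seed: int = 0,
    n: int = 30,
    kappa_hat: float = 4.0,
    delta_base: float = 0.5,
    cr_template: ContrastResponse | None = None,
    n_trials: int = 2000,
    maxiter: int = 150,
) -> tuple[PopulationCode, float]:
    """Maximize reward minus spike cost over (g_p, r_max).

    Same polynomial gain family as the algorithmic model; r_max (the peak of
    the contrast response, in spikes/trial) is log-parametrized. Returns the
    optimized population and its objective value.
    """
    if starts < 1:
        raise ValueError("starts must be >= 1")
    cr_template = cr_template or ContrastResponse(k_max=20.0)
    rng = np.random.default_rng(seed)
    step = float(prior.step)
    sim_seed = int(rng.integers(2**31 - 1))

    def build(x: np.ndarray) -> PopulationCode:
        gain = parametrize_g(x[:3], step=step)
        cr = ContrastResponse(k_max=float(np.exp(x[3])), q=cr_template.q, c50=cr_template.c50)
        return PopulationCode.build(prior, gain, cr, n=n, kappa_hat=kappa_hat, delta_base=delta_base)

    def fun(x: np.ndarray) -> float:
        try:
            pop = build(x)
        except InvalidCoefficientsError:
            return 1e6
        return -network_objective(
            pop, env, sigma_late, prior, contrasts, eta_spike, n_trials=n_trials, seed=sim_seed
        )

    x0s = [np.array([0.0, 0.0, 0.0, np.log(cr_template.k_max)])]
    while len(x0s) < starts:
        coeffs = rng.uniform(-2.0, 2.0, size=3)
        try:
            parametrize_g(coeffs, step=step)
        except InvalidCoefficientsError:
            continue
        x0s.append(np.r_[coeffs, rng.uniform(np.log(3.0), np.log(80.0))])
    best = None
    for x0 in x0s:
        res = minimize(fun, x0, method="Nelder-Mead", options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-4})
        if best is None or res.fun < best.fun:
            best = res
    return build(best.x), -float(best.fun)
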