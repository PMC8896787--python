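"""Endogenous optimization of the resource gain function.

The rational-inattention agent chooses how to distribute bounded encoding
precision over orientation space. Formally it minimizes

    expected reward loss(Omega, g, k_max, sigma_late)  +  cost

where the loss is the reward-weighted error probability averaged over the
task's stimulus and contrast distribution, and the cost is either
``eta * k_bar`` (linear in the average invested precision, the default) or
``eta * I(theta; m)`` (linear in the mutual information between stimulus and
measurement). The gain function is parametrized through a low-order
polynomial antiderivative G on the normalized half-domain (verticality axis),
mirrored to the full orientation circle, which spans smooth allocations with
three coefficients; g_p = (0,0,0) is the uniform allocation. Optimization is
derivative-free multi-start Nelder-Mead over (g_p, log k_max), with invalid
(non-monotone G) coefficients rejected by a large penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

from .observer import ObserverParams, ResourceGain, moment_table
from .stimulus import (
    CONTRAST_LEVELS,
    DIFFICULTY_SET,
    ContrastResponse,
    OrientationPrior,
    RewardEnvironment,
    orientation_grid,
    reward_environment,
    verticality,
)

__all__ = [
    "CostModel",
    "OptimizationResult",
    "parametrize_g",
    "average_precision",
    "mutual_information_cost",
    "StimulusPairSet",
    "expected_loss",
    "expected_reward",
    "overall_accuracy",
    "objective",
    "optimize",
    "reward_loss_on_swap",
    "swap_loss_experiment",
]

_PENALTY = 1e6


class InvalidCoefficientsError(ValueError):
    """G(theta) is not strictly increasing for these polynomial coefficients."""


@dataclass(frozen=True)
class CostModel:
    """Precision cost: eta per unit average precision, or per nat."""

    eta: float = 0.02
    kind: str = "precision"  # or "mutual_information"

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.kind not in ("precision", "mutual_information"):
            raise ValueError(f"unknown cost kind {self.kind!r}")


@dataclass(frozen=True)
class OptimizationResult:
    """Best allocation found over all starts, with its decomposition."""

    coeffs: tuple[float, float, float]
    k_max: float
    objective: float
    expected_reward: float
    expected_loss: float
    cost: float
    n_starts: int
    n_feasible: int
    start_objectives: tuple[float, ...]
    gain: ResourceGain


def parametrize_g(coeffs, step: float = 2.0) -> ResourceGain:
    """Resource gain from polynomial coefficients (g0, g1, g2).

    ``G(x) = x[1 + (x-1)(g0 + g1 x + g2 x^2)]`` on the normalized
    half-domain x in [0, 1]; g = G' sampled at the half-grid, mirrored about
    90 degrees to cover [0, 180), and renormalized to unit mean. Raises
    ``InvalidCoefficientsError`` if G is not strictly increasing (g would
    not be positive).
    """
    g0, g1, g2 = (float(v) for v in coeffs)
    grid = orientation_grid(step)
    half = grid.size // 2
    # midpoints of the half-domain cells, so the mirror is symmetric
    x = (np.arange(half) + 0.5) / half
    # G'(x) = 1 + (2x-1) g0 + (3x^2-2x) g1 + (4x^3-3x^2) g2
    gp = 1.0 + (2 * x - 1) * g0 + (3 * x**2 - 2 * x) * g1 + (4 * x**3 - 3 * x**2) * g2
    xf = np.linspace(0.0, 1.0, 257)
    gpf = 1.0 + (2 * xf - 1) * g0 + (3 * xf**2 - 2 * xf) * g1 + (4 * xf**3 - 3 * xf**2) * g2
    if np.any(gpf <= 0) or np.any(gp <= 0):
        raise InvalidCoefficientsError(f"G not strictly increasing for {coeffs}")
    full = np.concatenate([gp, gp[::-1]])
    full = full / full.mean()
    return ResourceGain(grid=grid, values=full, coeffs=(g0, g1, g2))


def average_precision(
    params: ObserverParams,
    prior: OrientationPrior,
    contrasts=CONTRAST_LEVELS,
) -> float:
    """k_bar: mean over contrasts of integral pi(theta) g(theta) k(c) dtheta."""
    if len(contrasts) == 0:
        raise ValueError("contrast set must be nonempty")
    gm = float(prior.density @ params.gain.values)
    return gm * float(np.mean([params.cr.k(c) for c in contrasts]))


def mutual_information_cost(
    params: ObserverParams,
    prior: OrientationPrior,
    contrasts=CONTRAST_LEVELS,
) -> float:
    """I(theta; m) in nats, averaged over the contrast set.

    Computed on the discrete grid from the joint p(theta, m) =
    pi(theta) p(m|theta); equals H(theta) - E[H(theta|m)], nonnegative.
    """
    from .observer import _check_grid
    from .stimulus import doubled

    grid = _check_grid(params, prior)
    psi = doubled(grid)
    dcos = np.cos(psi[:, None] - psi[None, :])
    vals = []
    for c in contrasts:
        conc = params.cr.k(c) * params.gain.values
        pm = np.exp(conc[:, None] * (dcos - 1.0))  # rows theta, cols m
        pm /= pm.sum(axis=1, keepdims=True)
        joint = prior.density[:, None] * pm
        pm_marg = joint.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(joint > 0, joint / (prior.density[:, None] * pm_marg[None, :]), 1.0)
            mi = float((joint * np.log(ratio)).sum())
        vals.append(mi)
    mi_mean = float(np.mean(vals))
    if mi_mean < -1e-9:
        raise FloatingPointError(f"negative mutual information {mi_mean}")
    return max(mi_mean, 0.0)


@dataclass(frozen=True)
class StimulusPairSet:
    """Discrete distribution over (theta_l, theta_r) pairs of the task.

    By default pairs are restricted to the task's difficulty set (absolute
    verticality differences of 20-90 degrees in 10-degree steps) on the
    orientation grid, weighted by pi(theta_l) pi(theta_r) and normalized.
    ``dense=True`` keeps every unequal pair instead.
    """

    il: np.ndarray  # grid indices, left
    ir: np.ndarray
    weights: np.ndarray  # sums to 1

    @classmethod
    def from_prior(
        cls,
        prior: OrientationPrior,
        difficulties=DIFFICULTY_SET,
        dense: bool = False,
    ) -> "StimulusPairSet":
        v = verticality(prior.grid)
        dv = np.abs(v[:, None] - v[None, :])
        if dense:
            mask = dv > 0
        else:
            mask = np.isclose(dv[:, :, None], np.asarray(difficulties)[None, None, :]).any(-1)
        il, ir = np.nonzero(mask)
        w = prior.density[il] * prior.density[ir]
        return cls(il=il, ir=ir, weights=w / w.sum())


def _loss_and_reward(
    env: RewardEnvironment,
    params: ObserverParams,
    prior: OrientationPrior,
    contrasts,
    pairs: StimulusPairSet,
) -> tuple[float, float]:
    """Expected (reward lost, reward gained) per trial in ul.

    The per-pair weight is the reward that a correct choice would deliver:
    max(R_l, R_r) when reward increases with verticality (the more vertical,
    correct side carries the larger reward), min(R_l, R_r) when it
    decreases, and the constant 5 ul otherwise.
    """
    r_l = np.asarray(env.reward_for(prior.grid))[pairs.il]
    r_r = np.asarray(env.reward_for(prior.grid))[pairs.ir]
    if env.env_id == "increasing":
        r_correct = np.maximum(r_l, r_r)
    elif env.env_id == "decreasing":
        r_correct = np.minimum(r_l, r_r)
    else:
        r_correct = r_l  # constant environment: 5 ul everywhere
    tables = {c: moment_table(params, prior, c) for c in contrasts}
    loss = 0.0
    reward = 0.0
    npairs = len(contrasts) ** 2
    for ci in contrasts:
        mean_i, var_i = tables[ci]
        for cj in contrasts:
            mean_j, var_j = tables[cj]
            dmu = np.abs(mean_i[pairs.il] - mean_j[pairs.ir])
            # tiny floor keeps the noiseless limit a step rule, not 0/0
            s = np.sqrt(
                np.maximum(var_i[pairs.il] + var_j[pairs.ir] + params.sigma_late**2, 1e-24)
            )
            perr = ndtr(-dmu / s)
            loss += float(np.sum(pairs.weights * r_correct * perr)) / npairs
            reward += float(np.sum(pairs.weights * r_correct * (1.0 - perr))) / npairs
    return loss, reward


def expected_loss(
    env: RewardEnvironment,
    params: ObserverParams,
    prior: OrientationPrior,
    contrasts=CONTRAST_LEVELS,
    pairs: StimulusPairSet | None = None,
) -> float:
    """Reward-weighted expected error probability, ul per trial."""
    pairs = pairs or StimulusPairSet.from_prior(prior)
    return _loss_and_reward(env, params, prior, contrasts, pairs)[0]


def expected_reward(
    env: RewardEnvironment,
    params: ObserverParams,
    prior: OrientationPrior,
    contrasts=CONTRAST_LEVELS,
    pairs: StimulusPairSet | None = None,
) -> float:
    """Expected collected reward, ul per trial, over the task distribution."""
    pairs = pairs or StimulusPairSet.from_prior(prior)
    return _loss_and_reward(env, params, prior, contrasts, pairs)[1]


def overall_accuracy(
    params: ObserverParams,
    prior: OrientationPrior,
    contrasts=CONTRAST_LEVELS,
    pairs: StimulusPairSet | None = None,
) -> float:
    """Mean P(correct) over the task's stimulus/contrast distribution."""
    pairs = pairs or StimulusPairSet.from_prior(prior)
    tables = {c: moment_table(params, prior, c) for c in contrasts}
    acc = 0.0
    npairs = len(contrasts) ** 2
    for ci in contrasts:
        mean_i, var_i = tables[ci]
        for cj in contrasts:
            mean_j, var_j = tables[cj]
            dmu = np.abs(mean_i[pairs.il] - mean_j[pairs.ir])
            s = np.sqrt(
                np.maximum(var_i[pairs.il] + var_j[pairs.ir] + params.sigma_late**2, 1e-24)
            )
            acc += float(np.sum(pairs.weights * ndtr(dmu / s))) / npairs
    return acc


def _cost(cost: CostModel, params, prior, contrasts) -> float:
    if cost.kind == "precision":
        return cost.eta * average_precision(params, prior, contrasts)
    return cost.eta * mutual_information_cost(params, prior, contrasts)


def objective(
    env: RewardEnvironment,
    cost: CostModel,
    params: ObserverParams,
    prior: OrientationPrior,
    contrasts=CONTRAST_LEVELS,
    pairs: StimulusPairSet | None = None,
) -> float:
    """Expected loss plus precision cost for a fully specified observer."""
    pairs = pairs or StimulusPairSet.from_prior(prior)
    return expected_loss(env, params, prior, contrasts, pairs) + _cost(
        cost, params, prior, contrasts
    )


def optimize(
    env: RewardEnvironment,
    cost: CostModel,
    sigma_late: float,
    prior: OrientationPrior,
    contrasts=CONTRAST_LEVELS,
    starts: int = 50,
    seed: int = 0,
    cr_template: ContrastResponse | None = None,
    step: float | None = None,
    maxiter: int = 400,
    dense: bool = False,
) -> OptimizationResult:
    """Find the optimal (g, k_max) for one environment.

    Multi-start Nelder-Mead over (g0, g1, g2, log k_max); each start is
    drawn from documented ranges (coefficients uniform in [-2, 2] resampled
    until feasible, log k_max uniform over [log 5, log 150]). k_max is
    log-parametrized to stay positive. ``dense=True`` integrates the loss
    over all unequal stimulus pairs (the continuous double integral on the
    grid) instead of the task's difficulty-restricted set. Returns the best
    converged start.
    """
    if starts < 1:
        raise ValueError("starts must be >= 1")
    step = step or float(prior.step)
    cr_template = cr_template or ContrastResponse()
    pairs = StimulusPairSet.from_prior(prior, dense=dense)
    rng = np.random.default_rng(seed)

    def make_params(x: np.ndarray) -> ObserverParams:
        gain = parametrize_g(x[:3], step=step)
        cr = ContrastResponse(k_max=float(np.exp(x[3])), q=cr_template.q, c50=cr_template.c50)
        return ObserverParams(gain=gain, cr=cr, sigma_late=sigma_late)

    def fun(x: np.ndarray) -> float:
        try:
            params = make_params(x)
        except InvalidCoefficientsError:
            return _PENALTY
        return objective(env, cost, params, prior, contrasts, pairs)

    best = None
    start_objs = []
    n_feasible = 0
    x0s = [np.array([0.0, 0.0, 0.0, np.log(cr_template.k_max)])]
    while len(x0s) < starts:
        coeffs = rng.uniform(-2.0, 2.0, size=3)
        try:
            parametrize_g(coeffs, step=step)
        except InvalidCoefficientsError:
            continue
        x0s.append(np.r_[coeffs, rng.uniform(np.log(5.0), np.log(150.0))])
    for x0 in x0s:
        res = minimize(fun, x0, method="Nelder-Mead", options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-7})
        start_objs.append(float(res.fun))
        if res.fun < _PENALTY / 2:
            n_feasible += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError(f"all {starts} starts infeasible for {env.env_id}")
    params = make_params(best.x)
    loss, reward = _loss_and_reward(env, params, prior, contrasts, pairs)
    c = _cost(cost, params, prior, contrasts)
    return OptimizationResult(
        coeffs=tuple(float(v) for v in best.x[:3]),
        k_max=float(np.exp(best.x[3])),
        objective=float(best.fun),
        expected_reward=reward,
        expected_loss=loss,
        cost=c,
        n_starts=starts,
        n_feasible=n_feasible,
        start_objectives=tuple(start_objs),
        gain=params.gain,
    )


def reward_loss_on_swap(
    env_a: RewardEnvironment,
    result_a: OptimizationResult,
    result_b: OptimizationResult,
    sigma_late: float,
    prior: OrientationPrior,
    contrasts=CONTRAST_LEVELS,
    cr_template: ContrastResponse | None = None,
) -> float:
    """Percent expected reward lost in env_a when using env_b's optimum.

    100 * (E[R | own optimum] - E[R | swapped optimum]) / E[R | own optimum];
    nonnegative up to optimizer tolerance.
    """
    cr_template = cr_template or ContrastResponse()
    pairs = StimulusPairSet.from_prior(prior)

    def params_from(res: OptimizationResult) -> ObserverParams:
        cr = ContrastResponse(k_max=res.k_max, q=cr_template.q, c50=cr_template.c50)
        return ObserverParams(gain=res.gain, cr=cr, sigma_late=sigma_late)

    r_own = expected_reward(env_a, params_from(result_a), prior, contrasts, pairs)
    r_swap = expected_reward(env_a, params_from(result_b), prior, contrasts, pairs)
    return 100.0 * (r_own - r_swap) / r_own


def swap_loss_experiment(
    eta: float = 0.2,
    sigma_late: float = 12.0,
    seed: int = 0,
    starts: int = 12,
    prior: OrientationPrior | None = None,
    cr_template: ContrastResponse | None = None,
) -> dict:
    """Cross-environment swap of optimal allocations, mouse-calibrated.

    Optimizes (g, k_max) for the increasing and decreasing reward
    environments with the full-integral loss at an encoding cost and late
    noise calibrated so task-distribution accuracy sits in the mouse-like
    70-80 % band, then evaluates the expected per-trial reward in each
    environment under its own optimum and under the other environment's
    optimum. The headline ``percent_loss`` is the increasing environment's
    loss under the decreasing environment's optimum.
    """
    prior = prior or OrientationPrior.horizontal_biased()
    cr_template = cr_template or ContrastResponse(k_max=30.0, q=2.0, c50=0.4)
    rng = np.random.default_rng(seed)
    cost = CostModel(eta=eta)
    env_inc = reward_environment("increasing")
    env_dec = reward_environment("decreasing")
    res_inc = optimize(
        env_inc, cost, sigma_late, prior, starts=starts,
        seed=int(rng.integers(2**31 - 1)), cr_template=cr_template, maxiter=800, dense=True,
    )
    res_dec = optimize(
        env_dec, cost, sigma_late, prior, starts=starts,
        seed=int(rng.integers(2**31 - 1)), cr_template=cr_template, maxiter=800, dense=True,
    )

    def params_from(res: OptimizationResult) -> ObserverParams:
        cr = ContrastResponse(k_max=res.k_max, q=cr_template.q, c50=cr_template.c50)
        return ObserverParams(gain=res.gain, cr=cr, sigma_late=sigma_late)

    loss_inc = reward_loss_on_swap(
        env_inc, res_inc, res_dec, sigma_late, prior, cr_template=cr_template
    )
    loss_dec = reward_loss_on_swap(
        env_dec, res_dec, res_inc, sigma_late, prior, cr_template=cr_template
    )
    acc_inc = overall_accuracy(params_from(res_inc), prior)
    acc_dec = overall_accuracy(params_from(res_dec), prior)
    return {
        "percent_loss": loss_inc,
        "loss_increasing": loss_inc,
        "loss_decreasing": loss_dec,
        "accuracy_increasing": acc_inc,
        "accuracy_decreasing": acc_dec,
        "result_increasing": res_inc,
        "result_decreasing": res_dec,
    }
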