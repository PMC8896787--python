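"""Confidence-gated distributional RL reallocation of the resource gain.

Instead of deriving the gain function g from a static optimization, the
learner maintains a reward-expectation vector R_hat over the orientation
grid (2-degree steps from 0 to 178). After each choice of orientation
theta_tilde with outcome R_t, a prediction-error vector is formed with a von
Mises kernel centered on the chosen orientation,

    delta_t(theta) = R_t - R_hat(theta_tilde) * exp(k_tilde*(cos(psi_tilde - psi) - 1)),

scaled by a learning rate that is gated by decision confidence C_t (the
model probability that the chosen option is correct) and is allowed to
differ for positive and negative prediction errors,

    alpha_t = C_t / (C_t + alpha_tilde_minus or _plus).

The belief is floored at zero and divisively normalized into the gain:
g = R_hat / sum(R_hat), which feeds back into the encoder on the next trial
(closed loop).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .observer import ObserverParams, ResourceGain, simulate_choices, choice_probabilities
from .stimulus import OrientationPrior, RewardEnvironment, doubled, verticality

__all__ = [
    "RewardBelief",
    "RLParams",
    "confidence",
    "learning_rate",
    "prediction_error_vector",
    "update_and_normalize",
    "run_session",
    "SessionTrajectory",
    "convergence_experiment",
]


@dataclass
class RewardBelief:
    """Nonnegative reward expectations (ul) over the orientation grid."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid/values shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("reward belief must be nonnegative")

    @classmethod
    def flat(cls, grid: np.ndarray, value: float = 5.0) -> "RewardBelief":
        """Uniform initialization at the constant-environment reward."""
        return cls(grid=grid, values=np.full(grid.size, float(value)))

    def gain(self) -> np.ndarray:
        """Divisively normalized gain, summing to one exactly."""
        s = self.values.sum()
        if s <= 0:
            raise ZeroDivisionError("degenerate reward belief: sum is zero")
        return self.values / s

    def resource_gain(self) -> ResourceGain:
        """Unit-mean ResourceGain for the encoder (unit-sum times grid size).

        Zero entries are lifted to a tiny floor so the gain stays a valid
        (strictly positive) precision allocation.
        """
        g = self.gain() * self.grid.size
        g = np.maximum(g, 1e-9)
        return ResourceGain(grid=self.grid, values=g / g.mean())


@dataclass(frozen=True)
class RLParams:
    """Divisive learning-rate constants, kernel concentration, update rule.

    Two prediction-error readings are provided. ``smoothed_error`` (default)
    spreads the scalar error at the chosen angle with the von Mises kernel,
    ``delta(theta) = (R_t - R_hat(theta_tilde)) * kernel``; it differentiates
    reward environments (the belief's fixed point tracks the local expected
    reward) and is the rule used by the closed-loop experiments.
    ``scaled_belief`` applies the kernel to the belief term only,
    ``delta(theta) = R_t - R_hat(theta_tilde) * kernel``; its fixed point is
    insensitive to the reward map (documented in the methods note).
    """

    alpha_plus: float = 0.5
    alpha_minus: float = 0.5
    k_tilde: float = 5.0
    rule: str = "smoothed_error"

    def __post_init__(self) -> None:
        if self.alpha_plus < 0 or self.alpha_minus < 0 or self.k_tilde <= 0:
            raise ValueError("require alpha_+/- >= 0 and k_tilde > 0")
        if self.rule not in ("smoothed_error", "scaled_belief"):
            raise ValueError(f"unknown update rule {self.rule!r}")


def confidence(trial, params: ObserverParams, prior: OrientationPrior) -> float:
    """C_t in (0.5, 1]: model probability that the chosen option is correct.

    Computed from the bias-free observer choice probability (biases reflect
    response tendencies, not evidence), hence never below chance.
    """
    unbiased = replace(params, beta0=0.0, beta1=0.0, beta2=0.0)
    p = float(choice_probabilities(pd.DataFrame([dict(trial)]), unbiased, prior)[0])
    return max(p, 1.0 - p)


def learning_rate(c_t: float, delta: float, params: RLParams) -> float:
    """Confidence-gated divisive learning rate in (0, 1]."""
    if not 0.0 < c_t <= 1.0:
        raise ValueError("confidence must lie in (0, 1]")
    a_tilde = params.alpha_minus if delta <= 0 else params.alpha_plus
    return c_t / (c_t + a_tilde)


def prediction_error_vector(
    reward: float, theta_chosen: float, belief: RewardBelief, params: RLParams
) -> np.ndarray:
    """delta_t(theta) over the grid, von Mises kernel at the chosen angle.

    Both rules reduce to ``R_t - R_hat(theta_tilde)`` at the chosen angle
    itself, where the kernel equals one.
    """
    i = int(np.rint(np.mod(theta_chosen, 180.0) / (belief.grid[1] - belief.grid[0]))) % belief.grid.size
    kernel = np.exp(params.k_tilde * (np.cos(doubled(belief.grid[i]) - doubled(belief.grid)) - 1.0))
    if params.rule == "scaled_belief":
        return reward - belief.values[i] * kernel
    return (reward - belief.values[i]) * kernel


def update_and_normalize(
    belief: RewardBelief,
    reward: float,
    theta_chosen: float,
    confidence_t: float,
    params: RLParams,
) -> tuple[RewardBelief, np.ndarray]:
    """One RL step: belief update, floor at zero, divisive normalization.

    Returns the new belief and the unit-sum gain vector.
    """
    delta = prediction_error_vector(reward, theta_chosen, belief, params)
    i = int(np.rint(np.mod(theta_chosen, 180.0) / (belief.grid[1] - belief.grid[0]))) % belief.grid.size
    alpha = learning_rate(confidence_t, float(reward - belief.values[i]), params)
    new_values = np.maximum(belief.values + alpha * delta, 0.0)
    new_belief = RewardBelief(grid=belief.grid, values=new_values)
    return new_belief, new_belief.gain()


@dataclass
class SessionTrajectory:
    """Closed-loop run record: per-trial gain vectors, beliefs, and behavior."""

    grid: np.ndarray
    gains: np.ndarray       # (n_trials, n_grid), unit-sum rows
    beliefs: np.ndarray     # (n_trials, n_grid)
    choices: np.ndarray
    rewards: np.ndarray
    confidences: np.ndarray

    def mean_gain(self, last: int | None = None) -> np.ndarray:
        sel = self.gains if last is None else self.gains[-last:]
        return sel.mean(axis=0)


def run_session(
    trials: pd.DataFrame,
    initial_belief: RewardBelief,
    observer: ObserverParams,
    params: RLParams,
    env: RewardEnvironment,
    prior: OrientationPrior,
    seed: int = 0,
) -> SessionTrajectory:
    """Closed-loop simulation over a stimuli-only trial stream.

    Each trial's choice is sampled from the observer using the gain derived
    from the current belief; the outcome updates the belief, which sets the
    gain for the next trial. Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    belief = initial_belief
    n = len(trials)
    ngrid = belief.grid.size
    gains = np.empty((n, ngrid))
    beliefs = np.empty((n, ngrid))
    choices = np.empty(n, dtype=object)
    rewards = np.empty(n)
    confidences = np.empty(n)
    for t in range(n):
        row = trials.iloc[[t]]
        obs_t = replace(observer, gain=belief.resource_gain())
        gains[t] = belief.gain()
        choice = simulate_choices(row, obs_t, prior, rng)[0]
        rec = row.iloc[0]
        v_l, v_r = verticality(float(rec["theta_l"])), verticality(float(rec["theta_r"]))
        chose_left = choice == "left"
        if np.isclose(v_l, v_r):
            correct = bool(rng.integers(0, 2))
        else:
            correct = (v_l > v_r) if chose_left else (v_r > v_l)
        theta_chosen = float(rec["theta_l"] if chose_left else rec["theta_r"])
        reward = float(env.reward_for(theta_chosen)) if correct else 0.0
        c_t = confidence(rec.to_dict(), obs_t, prior)
        belief, _ = update_and_normalize(belief, reward, theta_chosen, c_t, params)
        beliefs[t] = belief.values
        choices[t] = choice
        rewards[t] = reward
        confidences[t] = c_t
    return SessionTrajectory(
        grid=belief.grid,
        gains=gains,
        beliefs=beliefs,
        choices=choices.astype(str),
        rewards=rewards,
        confidences=confidences,
    )


def convergence_experiment(
    env_ids=("increasing", "decreasing", "constant"),
    eta: float = 0.6,
    sigma_late: float = 5.0,
    n_trials: int = 3000,
    last: int = 500,
    rl_params: RLParams | None = None,
    seed: int = 0,
    optimizer_starts: int = 10,
) -> dict:
    """Closed-loop RL runs vs the static optimum, per environment.

    For each environment the static optimum (g*, k_max*) is derived with
    the full-integral objective at the late-noise calibration; a closed-loop
    session then starts from a flat belief with the same contrast response
    and late noise, and the Spearman correlation between the last-``last``
    -trial mean gain and g* is reported alongside both gain profiles.
    """
    from scipy.stats import spearmanr

    from .resource import CostModel, optimize
    from .stimulus import ContrastResponse, OrientationPrior, reward_environment
    from .synthetic import SessionSpec, generate_trials

    rl_params = rl_params or RLParams(alpha_plus=0.3, alpha_minus=0.6, k_tilde=2.0)
    prior = OrientationPrior.horizontal_biased()
    cr_template = ContrastResponse(k_max=30.0, q=2.0, c50=0.4)
    rng = np.random.default_rng(seed)
    out = {}
    for env_id in env_ids:
        env = reward_environment(env_id)
        opt_seed, sess_seed, stream_seed = (int(rng.integers(2**31 - 1)) for _ in range(3))
        res = optimize(
            env,
            CostModel(eta=eta),
            sigma_late,
            prior,
            starts=optimizer_starts,
            seed=opt_seed,
            cr_template=cr_template,
            maxiter=800,
            dense=True,
        )
        observer = ObserverParams(
            gain=ResourceGain.uniform(),
            cr=ContrastResponse(k_max=res.k_max, q=cr_template.q, c50=cr_template.c50),
            sigma_late=sigma_late,
        )
        stream = generate_trials(SessionSpec(n_trials=n_trials, env_id=env_id, seed=stream_seed))
        traj = run_session(
            stream, RewardBelief.flat(prior.grid), observer, rl_params, env, prior, seed=sess_seed
        )
        mean_gain = traj.mean_gain(last=last)
        out[env_id] = {
            "spearman": float(spearmanr(mean_gain, res.gain.values).statistic),
            "mean_gain": mean_gain,
            "static_gain": res.gain.values / res.gain.values.sum(),
            "k_max": res.k_max,
        }
    return out
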