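"""Synthetic 2AFC sessions with known ground truth.

Emulates the orientation-discrimination task: on each trial the correct
(more vertical) orientation is drawn from the horizontal-heavy prior, the
angle difference is drawn from the task's difficulty set (20-90 degrees of
verticality in 10-degree steps, with a small fraction of equal-angle
trials), contrasts are drawn independently from {0.3, 0.6, 1}, and rewards
follow one of the three stimulus-reward environments. Choices are produced
either by the rational-inattention observer or by a descriptive model, so
every downstream stage (fitting, model comparison, learning) can be tested
against a known generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptive import DMParams, dm_choice_probabilities
from .observer import ObserverParams, simulate_choices
from .stimulus import (
    CONTRAST_LEVELS,
    DIFFICULTY_SET,
    OrientationPrior,
    TRIAL_COLUMNS,
    RewardEnvironment,
    reward_environment,
    validate_trial_table,
    verticality,
)

__all__ = ["SessionSpec", "generate_trials", "simulate_session", "write_trials", "read_trials"]

_MAX_RESAMPLE_ROUNDS = 1000


@dataclass(frozen=True)
class SessionSpec:
    """Specification of one synthetic session."""

    n_trials: int = 5000
    env_id: str = "constant"
    difficulties: tuple = DIFFICULTY_SET
    equal_angle_fraction: float = 0.02
    contrasts: tuple = CONTRAST_LEVELS
    prior_step: float = 2.0
    prior_concentration: float = 0.5
    observer: ObserverParams | None = None
    dm: DMParams | None = None
    repeat_incorrect: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        if not 0 <= self.equal_angle_fraction <= 1:
            raise ValueError("equal_angle_fraction must lie in [0, 1]")
        if any(d <= 0 or d > 90 for d in self.difficulties):
            raise ValueError("difficulties must lie in (0, 90] verticality degrees")

    def prior(self) -> OrientationPrior:
        return OrientationPrior.horizontal_biased(self.prior_step, self.prior_concentration)

    def environment(self) -> RewardEnvironment:
        return reward_environment(self.env_id)


def _draw_stimulus_pairs(
    spec: SessionSpec, prior: OrientationPrior, rng: np.random.Generator, n: int
):
    """Correct-side and distractor orientations for n unequal trials."""
    d = rng.choice(np.asarray(spec.difficulties, float), size=n)
    theta_c = np.full(n, np.nan)
    v_grid = verticality(prior.grid)
    # draw the correct side from the prior conditioned on feasibility
    # (verticality >= difficulty), exact equivalent of resampling rejections
    for dv in np.unique(d):
        sel = d == dv
        feasible = v_grid >= dv - 1e-9
        mass = prior.density[feasible]
        if mass.sum() <= 0:
            raise RuntimeError(f"no orientation can host difficulty {dv}")
        theta_c[sel] = rng.choice(prior.grid[feasible], size=int(sel.sum()), p=mass / mass.sum())
    v_other = verticality(theta_c) - d
    # two orientations share a verticality; pick a branch at random
    branch = rng.integers(0, 2, size=n).astype(bool)
    theta_o = np.where(branch & (v_other > 0), 180.0 - v_other, v_other)
    return theta_c, theta_o


def generate_trials(spec: SessionSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Stimuli-only trial table (theta_l, theta_r, c_l, c_r, env_id)."""
    rng = rng or np.random.default_rng(spec.seed)
    prior = spec.prior()
    n = spec.n_trials
    equal = rng.random(n) < spec.equal_angle_fraction
    n_uneq = int((~equal).sum())
    theta_l = np.empty(n)
    theta_r = np.empty(n)
    theta_c, theta_o = _draw_stimulus_pairs(spec, prior, rng, n_uneq)
    correct_left = rng.integers(0, 2, size=n_uneq).astype(bool)
    theta_l[~equal] = np.where(correct_left, theta_c, theta_o)
    theta_r[~equal] = np.where(correct_left, theta_o, theta_c)
    theta_eq = rng.choice(prior.grid, size=int(equal.sum()), p=prior.density)
    theta_l[equal] = theta_eq
    theta_r[equal] = theta_eq
    contrasts = np.asarray(spec.contrasts, float)
    df = pd.DataFrame(
        {
            "theta_l": theta_l,
            "theta_r": theta_r,
            "c_l": rng.choice(contrasts, size=n),
            "c_r": rng.choice(contrasts, size=n),
            "env_id": spec.env_id,
        }
    )
    validate_trial_table(df, require_choices=False)
    return df


def _settle_outcomes(
    df: pd.DataFrame, env: RewardEnvironment, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill correct/reward given choices; equal-angle trials reward a random side."""
    v_l = verticality(df["theta_l"].to_numpy(float))
    v_r = verticality(df["theta_r"].to_numpy(float))
    chose_l = (df["choice"] == "left").to_numpy()
    tie = np.isclose(v_l, v_r)
    lucky_left = rng.integers(0, 2, size=len(df)).astype(bool)
    correct = np.where(tie, chose_l == lucky_left, np.where(chose_l, v_l > v_r, v_r > v_l))
    theta_chosen = np.where(chose_l, df["theta_l"], df["theta_r"])
    reward = np.where(correct, np.asarray(env.reward_for(theta_chosen)), 0.0)
    df = df.copy()
    df["correct"] = correct
    df["reward"] = reward
    df["prev_choice"] = np.r_[["none"], df["choice"].to_numpy()[:-1]]
    df["prev_reward"] = np.r_[[0.0], reward[:-1]]
    return df


def _simulate_dm(df: pd.DataFrame, dm: DMParams, rng: np.random.Generator) -> np.ndarray:
    """Sequential DM simulation threading choice/reward history."""
    choices = []
    prev_choice = "none"
    prev_reward = 0.0
    for _, row in df.iterrows():
        rec = row.to_dict()
        rec["prev_choice"] = prev_choice
        rec["prev_reward"] = prev_reward
        p = float(dm_choice_probabilities(pd.DataFrame([rec]), dm)[0])
        choice = "left" if rng.random() < p else "right"
        choices.append(choice)
        prev_choice = choice
        # rewards filled afterwards; history term uses a provisional reward
        v_l, v_r = verticality(rec["theta_l"]), verticality(rec["theta_r"])
        chosen = rec["theta_l"] if choice == "left" else rec["theta_r"]
        won = (v_l > v_r) if choice == "left" else (v_r > v_l)
        env = reward_environment(rec["env_id"])
        prev_reward = float(env.reward_for(chosen)) if won else 0.0
    return np.asarray(choices)


def simulate_session(spec: SessionSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Full synthetic session: stimuli, choices, outcomes, history columns.

    Ground truth is the observer model if ``spec.observer`` is set, else the
    descriptive model ``spec.dm``. With ``repeat_incorrect`` every incorrect
    trial is followed by resampled same-side trials that are marked
    ``excluded=True`` (the analysis-set emulation of the rig's anti-bias
    protocol); fits should drop excluded rows.
    """
    if (spec.observer is None) == (spec.dm is None):
        raise ValueError("specify exactly one of observer or dm ground truth")
    rng = rng or np.random.default_rng(spec.seed)
    df = generate_trials(spec, rng)
    prior = spec.prior()
    env = spec.environment()
    if spec.observer is not None:
        df["choice"] = simulate_choices(df, spec.observer, prior, rng)
    else:
        df["choice"] = _simulate_dm(df, spec.dm, rng)
    df = _settle_outcomes(df, env, rng)
    df["excluded"] = False
    if spec.repeat_incorrect:
        df = _insert_repeats(df, spec, prior, env, rng)
    df = df[list(TRIAL_COLUMNS) + ["prev_reward", "excluded"]]
    validate_trial_table(df)
    return df.reset_index(drop=True)


def _insert_repeats(df, spec, prior, env, rng, max_repeats: int = 5):
    rows = []
    for _, row in df.iterrows():
        rows.append(row)
        attempts = 0
        cur = row
        while not cur["correct"] and attempts < max_repeats:
            attempts += 1
            rep_spec = SessionSpec(
                n_trials=1,
                env_id=spec.env_id,
                difficulties=spec.difficulties,
                equal_angle_fraction=0.0,
                contrasts=spec.contrasts,
                prior_step=spec.prior_step,
                prior_concentration=spec.prior_concentration,
                observer=spec.observer,
                dm=spec.dm,
            )
            rep = generate_trials(rep_spec, rng)
            # keep the correct side the same as the failed trial
            v_l = verticality(float(rep.loc[0, "theta_l"]))
            v_r = verticality(float(rep.loc[0, "theta_r"]))
            want_left = verticality(float(cur["theta_l"])) > verticality(float(cur["theta_r"]))
            if (v_l > v_r) != want_left:
                rep.loc[0, ["theta_l", "theta_r"]] = rep.loc[0, ["theta_r", "theta_l"]].to_numpy()
                rep.loc[0, ["c_l", "c_r"]] = rep.loc[0, ["c_r", "c_l"]].to_numpy()
            if spec.observer is not None:
                rep["choice"] = simulate_choices(rep, spec.observer, prior, rng)
            else:
                rep["choice"] = _simulate_dm(rep, spec.dm, rng)
            rep = _settle_outcomes(rep, env, rng)
            rep["excluded"] = True
            cur = rep.iloc[0]
            rows.append(cur)
    out = pd.DataFrame(rows).reset_index(drop=True)
    out["prev_choice"] = np.r_[["none"], out["choice"].to_numpy()[:-1]]
    out["prev_reward"] = np.r_[[0.0], out["reward"].to_numpy()[:-1]]
    return out


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with the canonical column order."""
    cols = [c for c in list(TRIAL_COLUMNS) + ["prev_reward", "excluded"] if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False)


def read_trials(path, require_choices: bool = True) -> pd.DataFrame:
    """Read and validate a trial-table CSV, enforcing column dtypes.

    Raises ``ValueError`` naming the missing column or the offending line.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pandas reports the line number
        raise ValueError(f"malformed trial table {path}: {exc}") from exc
    for col in ("theta_l", "theta_r", "c_l", "c_r"):
        if col not in df.columns:
            raise ValueError(f"trial table {path} missing column {col!r}")
        df[col] = df[col].astype(float)
    if "reward" in df.columns:
        df["reward"] = df["reward"].astype(float)
    if "correct" in df.columns:
        df["correct"] = df["correct"].astype(bool)
    if "excluded" in df.columns:
        df["excluded"] = df["excluded"].astype(bool)
    validate_trial_table(df, require_choices=require_choices)
    return df
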