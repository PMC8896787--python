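"""Orientation space, stimulus prior, contrast response, and reward environments.

Orientations live on [0, 180) degrees with the 180-degree periodicity of a
grating. All circular computations internally use the doubled angle
``psi = 2*theta`` in radians (period 2*pi), so that von Mises densities and
circular means are well defined on the orientation circle. The behavioral
decision rule operates in "verticality" space: the folded coordinate
``90 - |90 - theta|``, which maps 0 and 180 degrees to 0 (horizontal) and 90
degrees to 90 (vertical).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

ORIENTATION_PERIOD = 180.0
DEFAULT_GRID_STEP = 2.0
CONTRAST_LEVELS = (0.3, 0.6, 1.0)
#: angle differences used in the task, in verticality degrees
DIFFICULTY_SET = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)
ENV_IDS = ("constant", "increasing", "decreasing")

__all__ = [
    "ORIENTATION_PERIOD",
    "DEFAULT_GRID_STEP",
    "CONTRAST_LEVELS",
    "DIFFICULTY_SET",
    "ENV_IDS",
    "orientation_grid",
    "doubled",
    "verticality",
    "OrientationPrior",
    "RewardEnvironment",
    "reward_environment",
    "ContrastResponse",
    "validate_trial_table",
    "TRIAL_COLUMNS",
]


def orientation_grid(step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Regular orientation grid on [0, 180) degrees."""
    if step <= 0 or ORIENTATION_PERIOD % step:
        raise ValueError(f"step must be positive and divide 180, got {step}")
    return np.arange(0.0, ORIENTATION_PERIOD, step)


def doubled(theta_deg: np.ndarray | float) -> np.ndarray | float:
    """Doubled angle in radians: the orientation circle mapped to [0, 2*pi)."""
    return np.deg2rad(np.asarray(theta_deg, dtype=float) * 2.0)


def verticality(theta: np.ndarray | float) -> np.ndarray | float:
    """Fold an orientation into verticality degrees: ``90 - |90 - theta|``.

    0/180 deg -> 0 (horizontal); 90 deg -> 90 (vertical). Idempotent on
    [0, 90]. Raises for non-finite or out-of-range inputs.
    """
    th = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(th)):
        raise ValueError("orientation must be finite")
    if np.any(th < 0.0) or np.any(th > ORIENTATION_PERIOD):
        raise ValueError("orientation outside [0, 180] degrees")
    out = 90.0 - np.abs(90.0 - th)
    return float(out) if np.isscalar(theta) else out


@dataclass(frozen=True)
class OrientationPrior:
    """Discrete stimulus prior over the orientation grid.

    The density is probability *mass* per grid point (sums to one). The
    default construction is a horizontal-peaked von Mises density on the
    doubled-angle circle, so that horizontal orientations (0/180 deg) carry
    more mass than vertical (90 deg), with a configurable concentration.
    """

    grid: np.ndarray
    density: np.ndarray
    concentration: float = 0.5

    def __post_init__(self) -> None:
        if self.grid.shape != self.density.shape or self.grid.size == 0:
            raise ValueError("grid and density must be equal-length, nonempty")
        if np.any(self.density < 0):
            raise ValueError("prior density must be nonnegative")
        s = float(self.density.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"prior density must sum to 1, got {s}")

    @classmethod
    def horizontal_biased(
        cls, step: float = DEFAULT_GRID_STEP, concentration: float = 0.5
    ) -> "OrientationPrior":
        """Von Mises prior centered at horizontal on the doubled circle.

        With the default concentration 0.5 the horizontal-to-vertical mass
        ratio is e^(2*0.5) ~ 2.7, a horizontal-heavy environment.
        """
        grid = orientation_grid(step)
        w = np.exp(concentration * np.cos(doubled(grid)))
        return cls(grid=grid, density=w / w.sum(), concentration=concentration)

    @classmethod
    def uniform(cls, step: float = DEFAULT_GRID_STEP) -> "OrientationPrior":
        grid = orientation_grid(step)
        d = np.full(grid.size, 1.0 / grid.size)
        return cls(grid=grid, density=d, concentration=0.0)

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def index_of(self, theta: np.ndarray | float) -> np.ndarray | int:
        """Nearest grid index for an orientation (period-aware)."""
        th = np.mod(np.asarray(theta, dtype=float), ORIENTATION_PERIOD)
        idx = np.rint(th / self.step).astype(int) % self.grid.size
        return int(idx) if np.isscalar(theta) else idx


@dataclass(frozen=True)
class RewardEnvironment:
    """A stimulus-reward association rule Omega.

    Rewards for correct choices are a function of the verticality of the
    correct-side orientation: constant 5 ul; linearly increasing from 1 ul
    (horizontal) to 8 ul (vertical); or the reverse.
    """

    env_id: str
    reward_map: Callable[[float], float] = field(repr=False)

    def reward_for(self, theta: np.ndarray | float) -> np.ndarray | float:
        """Reward (ul) delivered for a correct choice of orientation theta."""
        v = verticality(theta)
        out = self.reward_map(np.asarray(v, dtype=float))
        return float(out) if np.isscalar(theta) else np.asarray(out)


def reward_environment(env_id: str) -> RewardEnvironment:
    """Construct one of the three task environments by name."""
    if env_id == "constant":
        return RewardEnvironment(env_id, lambda v: np.full_like(v, 5.0))
    if env_id == "increasing":
        return RewardEnvironment(env_id, lambda v: 1.0 + 7.0 * v / 90.0)
    if env_id == "decreasing":
        return RewardEnvironment(env_id, lambda v: 8.0 - 7.0 * v / 90.0)
    raise KeyError(f"unknown environment {env_id!r}; expected one of {ENV_IDS}")


@dataclass(frozen=True)
class ContrastResponse:
    """Naka-Rushton map from stimulus contrast to encoding precision.

    ``k(c) = k_max * c^q / (c^q + c50^q)`` -- the saturating contrast
    response of visual neurons, interpreted as a von Mises concentration
    (precision) on the doubled-angle circle.
    """

    k_max: float = 50.0
    q: float = 2.0
    c50: float = 0.5

    def __post_init__(self) -> None:
        if self.k_max <= 0 or self.q <= 0 or not (0.0 < self.c50 <= 1.0):
            raise ValueError(
                f"require k_max>0, q>0, 0<c50<=1; got {self.k_max}, {self.q}, {self.c50}"
            )

    def k(self, c: np.ndarray | float) -> np.ndarray | float:
        c_arr = np.asarray(c, dtype=float)
        if np.any(c_arr < 0):
            raise ValueError("contrast must be nonnegative")
        cq = c_arr**self.q
        out = self.k_max * cq / (cq + self.c50**self.q)
        return float(out) if np.isscalar(c) else out

    __call__ = k


#: required columns of a trial table, in canonical order
TRIAL_COLUMNS = (
    "theta_l",
    "theta_r",
    "c_l",
    "c_r",
    "env_id",
    "choice",
    "prev_choice",
    "reward",
    "correct",
)


def validate_trial_table(df, require_choices: bool = True) -> None:
    """Check the structural invariants of a trial table.

    Verifies orientations, contrast levels, environment ids, and -- when
    choices are present -- that rewards are positive exactly on correct (or
    equal-angle) trials. Raises ``ValueError`` naming the first violation.
    """
    needed = TRIAL_COLUMNS if require_choices else TRIAL_COLUMNS[:5]
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"trial table missing column {col!r}")
    for col in ("theta_l", "theta_r"):
        th = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(th)) or np.any(th < 0) or np.any(th >= 180.0):
            raise ValueError(f"{col} outside [0, 180)")
    for col in ("c_l", "c_r"):
        if not np.isin(df[col].to_numpy(dtype=float), CONTRAST_LEVELS).all():
            raise ValueError(f"{col} contains contrast outside {CONTRAST_LEVELS}")
    if not df["env_id"].isin(ENV_IDS).all():
        raise ValueError(f"env_id outside {ENV_IDS}")
    if not require_choices:
        return
    if not df["choice"].isin(("left", "right")).all():
        raise ValueError("choice must be 'left' or 'right'")
    if not df["prev_choice"].isin(("left", "right", "none")).all():
        raise ValueError("prev_choice must be 'left', 'right' or 'none'")
    v_l = verticality(df["theta_l"].to_numpy(dtype=float))
    v_r = verticality(df["theta_r"].to_numpy(dtype=float))
    tie = np.isclose(v_l, v_r)
    rewarded = df["reward"].to_numpy(dtype=float) > 0
    correct = df["correct"].to_numpy(dtype=bool)
    bad = np.flatnonzero(rewarded != correct)
    if bad.size:
        raise ValueError(f"reward/correct mismatch at row {bad[0]}")
    chose_l = (df["choice"] == "left").to_numpy()
    true_correct = np.where(chose_l, v_l > v_r, v_r > v_l)
    bad = np.flatnonzero(~tie & (correct != true_correct))
    if bad.size:
        raise ValueError(f"'correct' inconsistent with verticality rule at row {bad[0]}")
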