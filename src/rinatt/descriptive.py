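"""Descriptive probit choice models DM1-DM6 for the 2AFC task.

A family of nested psychometric models on the verticality difference of the
two gratings: DM1 has a single sensory noise SD; DM2 lets the noise depend
on contrast (one SD per contrast level); DM3 adds a contrast-difference bias
(apparent risk seeking/aversion); DM4 splits the lapse rate by response
side; DM5 adds a previous-trial reward-by-choice term; DM6 combines DM4 and
DM5. All models include a side bias, a previous-choice bias, and lapses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .observer import _prev_code
from .stimulus import CONTRAST_LEVELS, verticality

__all__ = ["DMParams", "MODEL_IDS", "dm_choice_probabilities", "dm_choice_probability", "dm_n_params"]

MODEL_IDS = ("DM1", "DM2", "DM3", "DM4", "DM5", "DM6")


@dataclass(frozen=True)
class DMParams:
    """Parameters of one descriptive model.

    ``sigma`` is a single SD (verticality degrees) for DM1 or a mapping
    contrast -> SD for DM2+. ``lapse`` is the symmetric lapse rate; DM4/DM6
    instead use side-specific ``lapse_l``/``lapse_r`` (the left-guess and
    right-guess rates).
    """

    model_id: str
    sigma: float | dict = 10.0
    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    lapse: float = 0.0
    lapse_l: float = 0.0
    lapse_r: float = 0.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id!r}")
        sig = self.sigma
        if self.model_id == "DM1":
            if not np.isscalar(sig) or sig <= 0:
                raise ValueError("DM1 needs a single positive sigma")
        else:
            if not isinstance(sig, dict):
                raise ValueError(f"{self.model_id} needs per-contrast sigmas")
            if any(s <= 0 for s in sig.values()):
                raise ValueError("sigmas must be positive")
        if self.model_id in ("DM4", "DM6"):
            if not (0 <= self.lapse_l and 0 <= self.lapse_r and self.lapse_l + self.lapse_r <= 1):
                raise ValueError("side lapses must be nonnegative with sum <= 1")
        elif not 0 <= self.lapse <= 1:
            raise ValueError("lapse must lie in [0, 1]")


def dm_n_params(model_id: str, n_contrasts: int = len(CONTRAST_LEVELS)) -> int:
    """Number of free parameters fitted for each descriptive model."""
    base = {
        "DM1": 1 + 2 + 1,                 # sigma, beta0, beta1, lapse
        "DM2": n_contrasts + 2 + 1,
        "DM3": n_contrasts + 3 + 1,       # + beta2
        "DM4": n_contrasts + 3 + 2,       # lapse_l, lapse_r
        "DM5": n_contrasts + 4 + 1,       # + beta3
        "DM6": n_contrasts + 4 + 2,
    }
    return base[model_id]


def dm_choice_probabilities(trials, params: DMParams) -> np.ndarray:
    """P(choose left) for every trial under the descriptive model.

    Probit on the verticality difference scaled by the combined sensory SD,
    plus the model's bias terms, mixed with the lapse rate(s). DM5/DM6
    require ``prev_reward`` (previous-trial reward, ul, 0 on first trials).
    """
    mid = params.model_id
    dv = verticality(trials["theta_l"].to_numpy(float)) - verticality(
        trials["theta_r"].to_numpy(float)
    )
    cl = trials["c_l"].to_numpy(float)
    cr = trials["c_r"].to_numpy(float)
    if mid == "DM1":
        s = params.sigma * np.sqrt(2.0)
        s = np.full(dv.shape, s)
    else:
        sig = params.sigma
        s = np.sqrt(
            np.array([sig[c] for c in cl]) ** 2 + np.array([sig[c] for c in cr]) ** 2
        )
    d_prev = _prev_code(trials["prev_choice"]) if "prev_choice" in trials else np.zeros(dv.shape)
    z = dv / s + params.beta0 + params.beta1 * d_prev
    if mid in ("DM3", "DM4", "DM5", "DM6"):
        z = z + params.beta2 * (cl - cr)
    if mid in ("DM5", "DM6"):
        if "prev_reward" not in trials:
            raise ValueError(f"{mid} requires a prev_reward column")
        z = z + params.beta3 * d_prev * trials["prev_reward"].to_numpy(float)
    p = ndtr(z)
    if mid in ("DM4", "DM6"):
        return p * (1.0 - params.lapse_l - params.lapse_r) + params.lapse_l
    return p * (1.0 - params.lapse) + params.lapse / 2.0


def dm_choice_probability(trial, params: DMParams) -> float:
    """Single-trial convenience wrapper around the vectorized form."""
    import pandas as pd

    return float(dm_choice_probabilities(pd.DataFrame([dict(trial)]), params)[0])
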