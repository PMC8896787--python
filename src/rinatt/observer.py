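"""Rational-inattention Bayesian observer for 2AFC orientation discrimination.

The observer receives, for each of the two gratings, a noisy internal
measurement ``m`` of the true orientation ``theta0``. The measurement is von
Mises distributed on the doubled-angle circle with concentration
``k(c) * g(theta0)``: the product of a saturating contrast response ``k(c)``
and a normalized resource gain function ``g`` that distributes bounded
encoding precision over orientation space. The observer decodes each
measurement with the Bayesian least-squares (BLS) rule -- the posterior mean
under the stimulus prior -- maps both estimates to verticality space, and
chooses the side with the larger estimate, corrupted by Gaussian late
(post-decoding) noise and optional side / history / contrast biases via a
probit rule.

Estimator moments ``E[theta_hat | theta0]`` and ``Var[theta_hat | theta0]``
are computed by integrating the decoder over the measurement distribution on
the grid. Two conventions are provided for where the circular estimate is
linearized: the default maps every decoded estimate to verticality first and
takes linear moments there (the space in which the probit decision rule
operates); the alternative takes circular moments on the doubled circle and
folds afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.special import i0e, ndtr

from .stimulus import (
    DEFAULT_GRID_STEP,
    ContrastResponse,
    OrientationPrior,
    doubled,
    orientation_grid,
    verticality,
)

__all__ = [
    "ResourceGain",
    "ObserverParams",
    "EstimatorMoments",
    "measurement_density",
    "decoder_table",
    "bls_estimate",
    "moment_table",
    "estimator_moments",
    "choice_probability",
    "choice_probabilities",
    "choice_prob_arrays",
    "error_probability",
    "simulate_choices",
]

MomentConvention = Literal["verticality", "circular"]


@dataclass(frozen=True)
class ResourceGain:
    """Normalized precision-allocation function g(theta) on the grid.

    Normalization is over the unit-normalized orientation domain
    (``integral g dx = 1`` with ``x = theta/180``), i.e. unit mean on the
    grid, so the uniform allocation is g = 1 everywhere and ``k(c)*g`` keeps
    the scale of a von Mises concentration.
    """

    grid: np.ndarray
    values: np.ndarray
    coeffs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.grid.shape != self.values.shape:
            raise ValueError("grid/values shape mismatch")
        if np.any(self.values <= 0):
            raise ValueError("resource gain must be strictly positive")
        m = float(self.values.mean())
        if abs(m - 1.0) > 1e-6:
            raise ValueError(f"resource gain must have unit mean, got {m}")

    @classmethod
    def uniform(cls, step: float = DEFAULT_GRID_STEP) -> "ResourceGain":
        grid = orientation_grid(step)
        return cls(grid=grid, values=np.ones(grid.size), coeffs=(0.0, 0.0, 0.0))

    def at(self, theta: np.ndarray | float) -> np.ndarray | float:
        """Gain at an orientation, by nearest grid point."""
        step = self.grid[1] - self.grid[0]
        idx = np.rint(np.mod(np.asarray(theta, float), 180.0) / step).astype(int)
        out = self.values[idx % self.grid.size]
        return float(out) if np.isscalar(theta) else out


@dataclass(frozen=True)
class ObserverParams:
    """Full parameter set of the rational-inattention observer.

    sigma_late is the SD (verticality degrees) of Gaussian noise added to
    the decision variable after decoding; beta0/beta1/beta2 are side,
    previous-choice, and contrast-difference biases on the probit argument.
    The lapse rate is fixed at zero in this model family.
    """

    gain: ResourceGain
    cr: ContrastResponse = field(default_factory=ContrastResponse)
    sigma_late: float = 5.0
    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_late < 0:
            raise ValueError("sigma_late must be >= 0")
        for b in (self.beta0, self.beta1, self.beta2):
            if not np.isfinite(b):
                raise ValueError("bias weights must be finite")

    def with_scales(self, k_scale: float = 1.0, late_scale: float = 1.0) -> "ObserverParams":
        """Covariate-modulated copy: multiply sensory precision k(c) by
        ``k_scale`` and late precision 1/sigma_late^2 by ``late_scale``."""
        if k_scale <= 0 or late_scale <= 0:
            raise ValueError("precision scales must be positive")
        return replace(
            self,
            cr=replace(self.cr, k_max=self.cr.k_max * k_scale),
            sigma_late=self.sigma_late / np.sqrt(late_scale),
        )


@dataclass(frozen=True)
class EstimatorMoments:
    """Mean and variance of the decoded estimate in verticality space."""

    mean: float
    var: float


def _check_grid(params: ObserverParams, prior: OrientationPrior) -> np.ndarray:
    if prior.grid.size == 0:
        raise ValueError("empty orientation grid")
    if prior.grid.size != params.gain.grid.size:
        raise ValueError("prior and gain must share the orientation grid")
    return prior.grid


def measurement_density(
    theta0: float, c: float, params: ObserverParams, prior: OrientationPrior
) -> np.ndarray:
    """p(m | theta0, c): von Mises mass over the measurement grid.

    Concentration ``k(c) * g(theta0)`` on the doubled circle; normalized to
    sum to one on the grid; uniform in the zero-concentration limit.
    """
    grid = _check_grid(params, prior)
    conc = params.cr.k(c) * params.gain.at(theta0)
    w = np.exp(conc * (np.cos(doubled(grid) - doubled(theta0)) - 1.0))
    return w / w.sum()


def decoder_table(
    params: ObserverParams, prior: OrientationPrior, c: float
) -> np.ndarray:
    """BLS estimate theta_hat(m), in degrees [0, 180), for every m on the grid.

    The posterior over theta combines the proper von Mises likelihood
    (including the theta-dependent normalizer, since the concentration
    k(c)*g(theta) varies with theta) with the stimulus prior; the estimate is
    the circular mean on the doubled circle mapped back to orientation.
    """
    grid = _check_grid(params, prior)
    psi = doubled(grid)
    conc = params.cr.k(c) * params.gain.values  # (T,)
    # L[m, t] = p(m | theta_t): exp(conc*cos(dpsi))/(2 pi I0(conc)),
    # written via i0e for overflow safety.
    dcos = np.cos(psi[:, None] - psi[None, :])  # rows m, cols theta
    lik = np.exp(conc[None, :] * (dcos - 1.0)) / i0e(conc)[None, :]
    post = lik * prior.density[None, :]
    norm = post.sum(axis=1)
    if np.any(norm <= 0) or np.any(~np.isfinite(norm)):
        raise FloatingPointError("degenerate posterior in BLS decoding")
    a = post @ np.sin(psi)
    b = post @ np.cos(psi)
    return np.mod(np.degrees(np.arctan2(a, b)) / 2.0, 180.0)


def bls_estimate(
    m: float, params: ObserverParams, prior: OrientationPrior, c: float
) -> float:
    """Posterior-mean (BLS) orientation estimate for a single measurement."""
    table = decoder_table(params, prior, c)
    return float(table[prior.index_of(m)])


def moment_table(
    params: ObserverParams,
    prior: OrientationPrior,
    c: float,
    convention: MomentConvention = "verticality",
) -> tuple[np.ndarray, np.ndarray]:
    """(mean, var) of the decoded estimate for every true theta0 on the grid.

    Means are in verticality degrees, variances in verticality degrees
    squared. ``convention='verticality'`` folds each decoded estimate to
    verticality before taking linear moments; ``'circular'`` takes circular
    moments on the doubled circle (mean by atan2, variance by -2 log R) and
    folds the mean afterwards.
    """
    grid = _check_grid(params, prior)
    psi = doubled(grid)
    theta_hat = decoder_table(params, prior, c)
    conc = params.cr.k(c) * params.gain.values
    dcos = np.cos(psi[:, None] - psi[None, :])  # rows theta0, cols m
    pm = np.exp(conc[:, None] * (dcos - 1.0))
    pm /= pm.sum(axis=1, keepdims=True)
    if convention == "verticality":
        v = verticality(theta_hat)
        mean = pm @ v
        var = pm @ (v**2) - mean**2
        var = np.maximum(var, 0.0)
    elif convention == "circular":
        a = pm @ np.sin(doubled(theta_hat))
        b = pm @ np.cos(doubled(theta_hat))
        r2 = a**2 + b**2
        if np.any(r2 <= 0):
            raise FloatingPointError("vanishing resultant in circular moments")
        mean = verticality(np.mod(np.degrees(np.arctan2(a, b)) / 2.0, 180.0))
        # -2 log(a^2+b^2) is the doubled-circle variance in rad^2; dividing
        # the angle by 2 and converting to degrees scales it by (90/pi)^2.
        var = -2.0 * np.log(r2) * (90.0 / np.pi) ** 2
    else:
        raise ValueError(f"unknown moment convention {convention!r}")
    return mean, var


def estimator_moments(
    theta0: float,
    c: float,
    params: ObserverParams,
    prior: OrientationPrior,
    convention: MomentConvention = "verticality",
) -> EstimatorMoments:
    """Moments of the decoded estimate for one (theta0, c) condition."""
    mean, var = moment_table(params, prior, c, convention)
    i = prior.index_of(theta0)
    return EstimatorMoments(mean=float(mean[i]), var=float(var[i]))


def _bias(params: ObserverParams, d_prev: np.ndarray, dc: np.ndarray) -> np.ndarray:
    return params.beta0 + params.beta1 * d_prev + params.beta2 * dc


def _prev_code(prev_choice) -> np.ndarray:
    """History regressor D: +1 after a left choice, -1 after right, 0 first."""
    arr = np.asarray(prev_choice)
    return np.where(arr == "left", 1.0, np.where(arr == "right", -1.0, 0.0))


def choice_prob_arrays(
    il: np.ndarray,
    ir: np.ndarray,
    cl: np.ndarray,
    cr_: np.ndarray,
    d_prev: np.ndarray,
    params: ObserverParams,
    prior: OrientationPrior,
    convention: MomentConvention = "verticality",
) -> np.ndarray:
    """P(choose left) from pre-extracted trial arrays (grid indices etc.)."""
    n = il.size
    tables = {
        c: moment_table(params, prior, c, convention) for c in np.unique(np.r_[cl, cr_])
    }
    mu_l = np.empty(n)
    var_l = np.empty(n)
    mu_r = np.empty(n)
    var_r = np.empty(n)
    for c, (mean, var) in tables.items():
        sel = cl == c
        mu_l[sel], var_l[sel] = mean[il[sel]], var[il[sel]]
        sel = cr_ == c
        mu_r[sel], var_r[sel] = mean[ir[sel]], var[ir[sel]]
    total_var = var_l + var_r + params.sigma_late**2
    if np.any(total_var < 0) or np.any(~np.isfinite(total_var)):
        raise FloatingPointError("invalid decision variance")
    # exactly noiseless observers degenerate to a step rule; a tiny floor
    # keeps the probit finite there
    s = np.sqrt(np.maximum(total_var, 1e-24))
    z = (mu_l - mu_r) / s + _bias(params, d_prev, cl - cr_)
    return ndtr(z)


def choice_probabilities(
    trials,
    params: ObserverParams,
    prior: OrientationPrior,
    convention: MomentConvention = "verticality",
) -> np.ndarray:
    """P(choose left) for every row of a trial table, vectorized.

    Probit rule on the difference of expected verticality estimates, scaled
    by total (estimator + late) SD, plus bias terms.
    """
    il = prior.index_of(trials["theta_l"].to_numpy(float))
    ir = prior.index_of(trials["theta_r"].to_numpy(float))
    cl = trials["c_l"].to_numpy(float)
    cr_ = trials["c_r"].to_numpy(float)
    d_prev = (
        _prev_code(trials["prev_choice"]) if "prev_choice" in trials else np.zeros(len(trials))
    )
    return choice_prob_arrays(il, ir, cl, cr_, d_prev, params, prior, convention)


def choice_probability(
    trial,
    params: ObserverParams,
    prior: OrientationPrior,
    convention: MomentConvention = "verticality",
) -> float:
    """P(choose left) for a single trial record (mapping or Series)."""
    import pandas as pd

    df = pd.DataFrame([dict(trial)])
    return float(choice_probabilities(df, params, prior, convention)[0])


def error_probability(
    theta_l: float,
    theta_r: float,
    c_l: float,
    c_r: float,
    params: ObserverParams,
    prior: OrientationPrior,
    convention: MomentConvention = "verticality",
) -> float:
    """Bias-free probability of choosing the less vertical side; <= 0.5."""
    ml = estimator_moments(theta_l, c_l, params, prior, convention)
    mr = estimator_moments(theta_r, c_r, params, prior, convention)
    s = np.sqrt(max(ml.var + mr.var + params.sigma_late**2, 1e-24))
    return float(ndtr(-abs(ml.mean - mr.mean) / s))


def simulate_choices(
    trials,
    params: ObserverParams,
    prior: OrientationPrior,
    rng: np.random.Generator,
    convention: MomentConvention = "verticality",
    return_estimates: bool = False,
):
    """Sample one choice per trial from the generative observer.

    For each side a measurement is drawn from the von Mises encoding
    distribution, decoded with the BLS table, and folded to verticality;
    Gaussian late noise is added to the difference and biases enter scaled
    by the trial's decision SD, so the Gaussian approximation of
    ``choice_probabilities`` is its analytic counterpart. When ``beta1`` is
    nonzero the history regressor is threaded through the simulated choice
    sequence. Returns an array of 'left'/'right' (and optionally the decoded
    verticality estimates per side).
    """
    n = len(trials)
    cl = trials["c_l"].to_numpy(float)
    cr_ = trials["c_r"].to_numpy(float)
    il = prior.index_of(trials["theta_l"].to_numpy(float))
    ir = prior.index_of(trials["theta_r"].to_numpy(float))
    contrasts = np.unique(np.r_[cl, cr_])
    dec = {c: decoder_table(params, prior, c) for c in contrasts}
    mom = {c: moment_table(params, prior, c, convention) for c in contrasts}

    def _sample_side(idx: np.ndarray, cs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        v_hat = np.empty(n)
        var = np.empty(n)
        for c in contrasts:
            sel = cs == c
            if not sel.any():
                continue
            conc = params.cr.k(c) * params.gain.values[idx[sel]]
            psi_m = rng.vonmises(doubled(prior.grid[idx[sel]]), conc)
            m_deg = np.mod(np.degrees(psi_m) / 2.0, 180.0)
            v_hat[sel] = verticality(dec[c][prior.index_of(m_deg)])
            var[sel] = mom[c][1][idx[sel]]
        return v_hat, var

    v_l, var_l = _sample_side(il, cl)
    v_r, var_r = _sample_side(ir, cr_)
    late = rng.normal(0.0, params.sigma_late, size=n)
    s = np.sqrt(np.maximum(var_l + var_r + params.sigma_late**2, 1e-24))
    dvar = v_l - v_r + late

    if params.beta1 == 0.0:
        d_prev = (
            _prev_code(trials["prev_choice"])
            if "prev_choice" in trials
            else np.zeros(n)
        )
        choose_left = dvar + s * _bias(params, d_prev, cl - cr_) > 0
    else:
        choose_left = np.empty(n, dtype=bool)
        d = 0.0
        for i in range(n):
            choose_left[i] = dvar[i] + s[i] * _bias(params, d, cl[i] - cr_[i]) > 0
            d = 1.0 if choose_left[i] else -1.0
    choices = np.where(choose_left, "left", "right")
    if return_estimates:
        return choices, v_l, v_r
    return choices
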