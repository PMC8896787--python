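"""Psychometric summaries and MDS geometry of discriminability.

The psychometric curve bins trials by the signed verticality difference and
reports the fraction of rightward choices with binomial standard errors. For
the geometric analysis, pairwise "psychometric distances" -- the probability
of a correct discrimination between two orientations minus 0.5, so that the
diagonal is exactly zero -- are embedded with classical (metric)
multidimensional scaling: double-centering of squared distances followed by
an eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observer import ObserverParams, error_probability
from .stimulus import CONTRAST_LEVELS, OrientationPrior, verticality

__all__ = [
    "psychometric_curve",
    "DissimilarityMatrix",
    "build_dissimilarity",
    "build_dissimilarity_from_trials",
    "classical_mds",
    "stress",
]


def psychometric_curve(trials: pd.DataFrame, bins=None) -> pd.DataFrame:
    """Choice fractions vs signed verticality difference (right minus left).

    Returns one row per bin with the bin center, fraction of rightward
    choices, binomial SE, and trial count; empty bins are reported with NaN
    fraction rather than zero.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    dv = verticality(trials["theta_r"].to_numpy(float)) - verticality(
        trials["theta_l"].to_numpy(float)
    )
    if bins is None:
        bins = np.arange(-95.0, 96.0, 10.0)
    bins = np.asarray(bins, float)
    chose_right = (trials["choice"] == "right").to_numpy()
    idx = np.digitize(dv, bins) - 1
    centers = (bins[:-1] + bins[1:]) / 2.0
    rows = []
    for b, center in enumerate(centers):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            rows.append({"dv": center, "p_right": np.nan, "se": np.nan, "n": 0})
            continue
        p = float(chose_right[sel].mean())
        rows.append({"dv": center, "p_right": p, "se": float(np.sqrt(p * (1 - p) / n)), "n": n})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric psychometric-distance matrix over an angle grid."""

    angles: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (self.angles.size, self.angles.size):
            raise ValueError("matrix shape must match angle grid")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")


def build_dissimilarity(
    params: ObserverParams,
    prior: OrientationPrior,
    angles: np.ndarray | None = None,
    contrasts=CONTRAST_LEVELS,
) -> DissimilarityMatrix:
    """Model-derived matrix: P(correct discrimination) - 0.5 per angle pair.

    Error probabilities are averaged over the contrast-pair product; entries
    lie in [0, 0.5] with an exactly zero diagonal.
    """
    angles = np.arange(0.0, 180.0, 10.0) if angles is None else np.asarray(angles, float)
    n = angles.size
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            perr = np.mean(
                [
                    error_probability(angles[i], angles[j], ci, cj, params, prior)
                    for ci in contrasts
                    for cj in contrasts
                ]
            )
            vals[i, j] = vals[j, i] = 0.5 - perr
    return DissimilarityMatrix(angles=angles, values=vals)


def build_dissimilarity_from_trials(
    trials: pd.DataFrame, angles: np.ndarray | None = None
) -> DissimilarityMatrix:
    """Trial-pooled matrix: empirical P(correct) - 0.5 per unordered pair.

    Raises if some pair of distinct angles was never presented.
    """
    angles = np.arange(0.0, 180.0, 10.0) if angles is None else np.asarray(angles, float)
    th_l = trials["theta_l"].to_numpy(float)
    th_r = trials["theta_r"].to_numpy(float)
    correct = trials["correct"].to_numpy(bool)
    n = angles.size
    vals = np.zeros((n, n))
    v = verticality(angles)
    for i in range(n):
        for j in range(i + 1, n):
            if np.isclose(v[i], v[j]):
                continue  # same verticality: no defined discrimination
            sel = (np.isclose(th_l, angles[i]) & np.isclose(th_r, angles[j])) | (
                np.isclose(th_l, angles[j]) & np.isclose(th_r, angles[i])
            )
            if not sel.any():
                raise ValueError(
                    f"no trials for pair ({angles[i]}, {angles[j]}) and no model fallback"
                )
            vals[i, j] = vals[j, i] = float(correct[sel].mean()) - 0.5
    return DissimilarityMatrix(angles=angles, values=vals)


def classical_mds(matrix: DissimilarityMatrix, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of the dissimilarities.

    Double-centers the squared distances, eigendecomposes, and keeps the
    ``dims`` leading nonnegative components. The sign of each axis is fixed
    deterministically (largest-magnitude loading positive) so repeated runs
    and permuted inputs give reproducible orientations.
    """
    d = matrix.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w = np.clip(w[:dims], 0.0, None)
    coords = v[:, :dims] * np.sqrt(w)[None, :]
    for k in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, k])))
        if coords[i, k] < 0:
            coords[:, k] *= -1
    return coords


def stress(matrix: DissimilarityMatrix, coords: np.ndarray) -> float:
    """Kruskal stress-1 between embedding distances and dissimilarities."""
    from scipy.spatial.distance import pdist, squareform

    dhat = squareform(pdist(coords))
    num = float(np.sum((matrix.values - dhat) ** 2))
    den = float(np.sum(matrix.values**2))
    return float(np.sqrt(num / den)) if den > 0 else 0.0
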