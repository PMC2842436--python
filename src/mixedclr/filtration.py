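"""Knock-out / knock-down filtration of least-likely regulatory edges.

If deleting a candidate regulator j barely moves target i away from its
wild-type level, and halving j's dosage doesn't move it either, the edge
j -> i is unlikely to be real.  For each ordered pair we measure the
relative perturbation response

    delta_ko[i, j] = |x_i(KO of j) - x_i^wt| / x_i^wt
    delta_kd[i, j] = |x_i(KD of j) - x_i^wt| / x_i^wt

and drop the edge iff both changes fall below a cutoff theta, by setting
its confidence score to -1 (sent to the tail of the ranked list).
Absolute change is used because knocking out a repressor *raises* its
target.  If only one of the two perturbation blocks is available, that
block alone decides.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .io import ExpressionDataset

__all__ = ["relative_change", "relative_change_matrix", "ko_kd_filter", "theta_for_fraction", "KnockoutFilter"]

logger = logging.getLogger(__name__)

FILTERED_SCORE = -1.0
DEFAULT_FILTER_FRACTION = 1.0 / 3.0
"""Default operating point: choose theta so about one third of ordered pairs are filtered."""


def relative_change(
    dataset: ExpressionDataset, regulator: int, target: int, which: str
) -> float:
    """Relative change of target i's steady state when regulator j is perturbed."""
    if which == "ko":
        block = dataset.knockout
    elif which == "kd":
        block = dataset.knockdown
    else:
        raise ValueError("which must be 'ko' or 'kd'")
    if block is None:
        raise ValueError(f"{which} block is not available")
    if dataset.wildtype is None:
        raise ValueError("wild-type block is not available")
    wt = dataset.wildtype[target]
    perturbed = block[regulator, target]
    diff = abs(perturbed - wt)
    if wt == 0:
        return math.inf if diff > 0 else 0.0
    return diff / wt


def relative_change_matrix(dataset: ExpressionDataset, which: str) -> np.ndarray:
    """All relative changes at once; entry [i, j] follows the target-row convention."""
    block = dataset.knockout if which == "ko" else dataset.knockdown
    if block is None:
        raise ValueError(f"{which} block is not available")
    if dataset.wildtype is None:
        raise ValueError("wild-type block is not available")
    wt = dataset.wildtype
    diff = np.abs(block - wt[None, :]).T  # [i, j]: target i under perturbation of j
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = diff / wt[:, None]
    delta = np.where(wt[:, None] > 0, delta, np.where(diff > 0, np.inf, 0.0))
    return delta


def _small_change_mask(dataset: ExpressionDataset, theta: float) -> np.ndarray:
    """True where every available perturbation of j moved i by less than theta."""
    masks = []
    for which in ("ko", "kd"):
        block = dataset.knockout if which == "ko" else dataset.knockdown
        if block is not None:
            masks.append(relative_change_matrix(dataset, which) < theta)
    if not masks:
        raise ValueError("neither knock-out nor knock-down block is available")
    mask = masks[0]
    for m in masks[1:]:
        mask &= m
    np.fill_diagonal(mask, False)
    return mask


def ko_kd_filter(m1: np.ndarray, dataset: ExpressionDataset, theta: float) -> np.ndarray:
    """Set scores of edges whose KO and KD responses both fall below theta to -1."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    m1 = np.asarray(m1, dtype=float)
    if theta == 0:
        return m1.copy()
    mask = _small_change_mask(dataset, theta)
    m2 = m1.copy()
    m2[mask] = FILTERED_SCORE
    logger.info(
        "filtration: removed %d of %d ordered pairs", mask.sum(), mask.size - mask.shape[0]
    )
    return m2


def theta_for_fraction(dataset: ExpressionDataset, fraction: float) -> float:
    """Cutoff theta filtering approximately ``fraction`` of all ordered pairs.

    theta is placed halfway between the order statistics of the combined
    perturbation response (the larger of KO and KD change per pair)
    bracketing the requested count.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return 0.0
    combined = []
    for which in ("ko", "kd"):
        block = dataset.knockout if which == "ko" else dataset.knockdown
        if block is not None:
            combined.append(relative_change_matrix(dataset, which))
    if not combined:
        raise ValueError("neither knock-out nor knock-down block is available")
    stat = np.maximum.reduce(combined)
    n = stat.shape[0]
    off = stat[~np.eye(n, dtype=bool)]
    off = np.sort(off[np.isfinite(off)])
    k = int(round(fraction * n * (n - 1)))
    if k <= 0:
        return 0.0
    if k >= off.size:
        return float(off[-1]) * (1 + 1e-9) + 1e-12
    return float((off[k - 1] + off[k]) / 2.0)


class KnockoutFilter(BaseEstimator):
    """Filter step as a transformer over confidence matrices.

    Exactly one of ``theta`` (absolute cutoff) or ``filter_fraction``
    (quantile-targeting surrogate; default about one third of ordered
    pairs) is used: an explicit ``theta`` wins.

    Attributes
    ----------
    theta_ : float
        The cutoff actually applied.
    n_filtered_ : int
        Number of ordered pairs sent to the list tail.
    """

    def __init__(self, theta: float | None = None, filter_fraction: float | None = None):
        self.theta = theta
        self.filter_fraction = filter_fraction

    def fit(self, X: ExpressionDataset, y=None) -> "KnockoutFilter":
        if self.theta is not None and self.filter_fraction is not None:
            raise ValueError("theta and filter_fraction are mutually exclusive")
        if self.theta is not None:
            self.theta_ = float(self.theta)
            if self.theta_ < 0:
                raise ValueError("theta must be >= 0")
        else:
            fraction = (
                DEFAULT_FILTER_FRACTION if self.filter_fraction is None else self.filter_fraction
            )
            self.theta_ = theta_for_fraction(X, fraction)
        self.dataset_ = X
        if self.theta_ > 0:
            self.mask_ = _small_change_mask(X, self.theta_)
        else:
            n = X.n_genes
            self.mask_ = np.zeros((n, n), dtype=bool)
        self.n_filtered_ = int(self.mask_.sum())
        return self

    def transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != self.mask_.shape:
            raise ValueError("score matrix shape differs from fitted dataset")
        out = scores.copy()
        out[self.mask_] = FILTERED_SCORE
        return out
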