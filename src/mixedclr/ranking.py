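"""Combining regression weights with CLR confidences into the final ranking.

Regression weights and pseudo z-scores live on incomparable scales, so the
kinetic weight matrix is converted to confidences by *rank substitution*:
the k-th largest |beta| receives the k-th largest strictly positive value
of the filtered confidence matrix (matrix-wide).  Adding the substituted
confidences back onto the filtered matrix doubles the score of edges
supported by both methods, pushing them up the final list, while leaving
all other edges in place.
"""

from __future__ import annotations

import numpy as np

from .io import RankedEdgeList

__all__ = ["weights_to_confidences", "final_scores", "to_ranked_list", "rank_by_weights"]


def weights_to_confidences(weights: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Replace nonzero |weights| by equal-rank strictly positive values of m2.

    Ties in |weight| are broken by (regulator, target) index order.  The
    substituted values are drawn from the whole matrix, with duplicate
    values consumed with multiplicity.
    """
    weights = np.asarray(weights, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if weights.shape != m2.shape:
        raise ValueError("weight and confidence matrices must share shape")
    targets, regulators = np.nonzero(weights)
    entries = sorted(
        zip(np.abs(weights[targets, regulators]), regulators, targets),
        key=lambda e: (-e[0], e[1], e[2]),
    )
    positive = np.sort(m2[m2 > 0])[::-1]
    if len(entries) > positive.size:
        raise ValueError(
            "more nonzero weights than strictly positive confidence scores"
        )
    conf = np.zeros_like(m2)
    for k, (_, j, i) in enumerate(entries):
        conf[i, j] = positive[k]
    return conf


def final_scores(m2: np.ndarray, confidences: np.ndarray) -> np.ndarray:
    """Final confidence matrix: elementwise sum of m2 and the substituted confidences."""
    m2 = np.asarray(m2, dtype=float)
    confidences = np.asarray(confidences, dtype=float)
    if m2.shape != confidences.shape:
        raise ValueError("shape mismatch")
    return m2 + confidences


def to_ranked_list(m3: np.ndarray) -> RankedEdgeList:
    """All ordered pairs sorted by score descending; ties by (regulator, target) index."""
    m3 = np.asarray(m3, dtype=float)
    n = m3.shape[0]
    edges = sorted(
        ((j, i, float(m3[i, j])) for i in range(n) for j in range(n) if i != j),
        key=lambda e: (-e[2], e[0], e[1]),
    )
    return RankedEdgeList(n_genes=n, edges=edges)


def rank_by_weights(weights: np.ndarray) -> RankedEdgeList:
    """Regression-only baseline ranking: |beta| descending, unselected edges after.

    Unselected pairs share score 0 and follow all selected edges in
    (regulator, target) index order.
    """
    weights = np.asarray(weights, dtype=float)
    return to_ranked_list(np.abs(weights))
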