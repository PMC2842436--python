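"""Scoring ranked edge predictions against a known network.

Precision-recall is the primary metric: a network-inference method should
produce few false positives even at the cost of missing edges, and AUPR
degrades quickly with early false positives.  ROC, a directionality
(causality-resolution) statistic and a relative-rank-error-by-degree
analysis complete the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GoldStandard, RankedEdgeList

__all__ = [
    "pr_curve",
    "roc_curve",
    "causality_fraction",
    "error_vs_degree",
    "degree_error_correlation",
    "PRResult",
    "ROCResult",
    "CausalityResult",
]


@dataclass
class PRResult:
    precision: np.ndarray
    recall: np.ndarray
    aupr: float
    precision_at_recall: dict[float, float]


@dataclass
class ROCResult:
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float


@dataclass
class CausalityResult:
    fraction: float
    n_correct: int
    n_incorrect: int
    n_identified: int


def _tp_flags(ranked: RankedEdgeList, gold: GoldStandard) -> np.ndarray:
    if gold.n_edges == 0:
        raise ValueError("gold standard has no positive edges")
    return np.array([(j, i) in gold.edges for j, i, _ in ranked.edges], dtype=bool)


def pr_curve(
    ranked: RankedEdgeList,
    gold: GoldStandard,
    recall_points: tuple[float, ...] = (),
) -> PRResult:
    """Precision and recall at every list prefix, with stepwise AUPR.

    The area sums precision at each prefix that adds a true positive,
    weighted by the recall increment it achieves (precision is held
    constant between achieved recall points).
    """
    flags = _tp_flags(ranked, gold)
    tp = np.cumsum(flags)
    k = np.arange(1, len(flags) + 1)
    precision = tp / k
    recall = tp / gold.n_edges
    aupr = float(np.sum(precision[flags]) / gold.n_edges)
    at = {}
    for r in recall_points:
        idx = np.nonzero(recall >= r)[0]
        at[r] = float(precision[idx[0]]) if idx.size else 0.0
    return PRResult(precision=precision, recall=recall, aupr=aupr, precision_at_recall=at)


def roc_curve(ranked: RankedEdgeList, gold: GoldStandard) -> ROCResult:
    """True/false positive rates over list prefixes; AUROC by the trapezoid rule."""
    flags = _tp_flags(ranked, gold)
    n_pos = gold.n_edges
    n_neg = len(flags) - n_pos
    if n_neg == 0:
        raise ValueError("gold standard has no negative pairs")
    tpr = np.concatenate([[0.0], np.cumsum(flags) / n_pos])
    fpr = np.concatenate([[0.0], np.cumsum(~flags) / n_neg])
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCResult(tpr=tpr, fpr=fpr, auroc=auroc)


def causality_fraction(scores: np.ndarray, gold: GoldStandard) -> CausalityResult:
    """Fraction of identified true edges scored strictly above their reversal.

    A true edge j -> i counts as *identified* when its score is positive
    (filtered edges carry -1, unscored ones 0); it is correctly resolved
    when score[i, j] > score[j, i].  Ties count as unresolved, so exactly
    symmetric scores resolve nothing.
    """
    scores = np.asarray(scores, dtype=float)
    n_correct = 0
    n_identified = 0
    for j, i in gold.edges:
        if scores[i, j] > 0:
            n_identified += 1
            if scores[i, j] > scores[j, i]:
                n_correct += 1
    fraction = n_correct / n_identified if n_identified else 0.0
    return CausalityResult(
        fraction=fraction,
        n_correct=n_correct,
        n_incorrect=n_identified - n_correct,
        n_identified=n_identified,
    )


def error_vs_degree(ranked: RankedEdgeList, gold: GoldStandard) -> dict:
    """Relative rank (rank / K) of every true edge, grouped by node degree.

    Returns per-edge errors together with groupings by the target's
    in-degree and the regulator's out-degree, plus network-level medians.
    """
    n = ranked.n_genes
    total = n * (n - 1)
    ranks = ranked.ranks()
    in_degree = np.zeros(n, dtype=int)
    out_degree = np.zeros(n, dtype=int)
    for j, i in gold.edges:
        in_degree[i] += 1
        out_degree[j] += 1
    errors = []
    by_in: dict[int, list[float]] = {}
    by_out: dict[int, list[float]] = {}
    for j, i in sorted(gold.edges):
        err = ranks[(j, i)] / total
        errors.append(err)
        by_in.setdefault(int(in_degree[i]), []).append(err)
        by_out.setdefault(int(out_degree[j]), []).append(err)
    errors = np.array(errors)
    return {
        "errors": errors,
        "median_error": float(np.median(errors)),
        "by_in_degree": {k: np.array(v) for k, v in sorted(by_in.items())},
        "by_out_degree": {k: np.array(v) for k, v in sorted(by_out.items())},
        "median_in_degree": float(np.median(in_degree[in_degree > 0])),
        "median_out_degree": float(np.median(out_degree[out_degree > 0])),
    }


def degree_error_correlation(results: list[dict], which: str = "in") -> float:
    """Spearman correlation of per-network median error with median degree.

    ``results`` are :func:`error_vs_degree` outputs for an ensemble of
    networks; ``which`` selects in- or out-degree.
    """
    key = f"median_{which}_degree"
    degrees = [r[key] for r in results]
    errors = [r["median_error"] for r in results]
    rho, _ = stats.spearmanr(degrees, errors)
    return float(rho)
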