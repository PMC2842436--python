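"""Per-target sparse ODE regression (Inferelator-style model selection).

For each target gene i we regress its ODE response vector y_i on the
time-lagged expression of a small candidate set R_i of regulators (the
up-to-P highest strictly positive confidence scores from the filtered CLR
matrix), under an L1 constraint expressed relative to the unpenalised
least-squares fit:

    minimise ||y_i - X beta||^2   subject to   sum|beta| <= s * sum|beta_ols|

with shrinkage s in [0, 1]: s=1 recovers ordinary least squares, s=0 the
all-zero model.  The constrained solution is read off the LARS-lasso
path, which is piecewise linear in the constraint bound.  s is chosen per
target by 10-fold cross validation; the default selection rule takes the
smallest s whose mean held-out error is within one standard error of the
minimum, operationalising "the minimum s with good generalisation".

Fold assignment keeps all transitions of a time-series experiment in the
same fold (temporally adjacent rows leak information across folds
otherwise).  There is no intercept: the ODE has no basal term here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import lars_path

from .design import DEFAULT_TAU, DesignPairs, build_dynamic_pairs
from .io import ExpressionDataset

__all__ = [
    "ShrinkageSpec",
    "select_candidates",
    "lasso_path_coef",
    "cv_select_shrinkage",
    "Inferelator",
    "fit_all_targets",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_REGULATORS = 10
DEFAULT_S_GRID = np.round(np.linspace(0.0, 1.0, 21), 2)


@dataclass
class ShrinkageSpec:
    """Cross-validation settings for choosing the shrinkage parameter s."""

    grid: np.ndarray = field(default_factory=lambda: DEFAULT_S_GRID.copy())
    folds: int = 10
    seed: int = 0
    rule: str = "1se"  # '1se' | 'min'

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any((self.grid < 0) | (self.grid > 1)):
            raise ValueError("shrinkage grid values must lie in [0, 1]")
        if np.any(np.diff(self.grid) < 0):
            raise ValueError("shrinkage grid must be sorted")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.rule not in {"1se", "min"}:
            raise ValueError("rule must be '1se' or 'min'")


def select_candidates(m2: np.ndarray, target: int, max_regulators: int = DEFAULT_MAX_REGULATORS) -> list[int]:
    """Up-to-P regulators with the largest strictly positive scores for one target.

    Ties at the cutoff are broken toward the lowest gene index; the
    target itself is never a candidate (no auto-regulation).
    """
    if max_regulators < 1:
        raise ValueError("max_regulators must be >= 1")
    row = np.asarray(m2, dtype=float)[target]
    order = sorted(
        (j for j in range(len(row)) if j != target and row[j] > 0),
        key=lambda j: (-row[j], j),
    )
    return order[:max_regulators]


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimum-L2-norm least-squares solution (deterministic under rank deficiency)."""
    return np.linalg.lstsq(X, y, rcond=None)[0]


def lasso_path_coef(y: np.ndarray, X: np.ndarray, s: float) -> np.ndarray:
    """L1-constrained least-squares coefficients at relative shrinkage s."""
    if not (0.0 <= s <= 1.0):
        raise ValueError("shrinkage s must lie in [0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if X.shape[1] == 0:
        return np.zeros(0)
    ols = _ols(X, y)
    if s == 1.0:
        return ols
    bound = s * np.abs(ols).sum()
    if bound == 0.0:
        return np.zeros(X.shape[1])
    _, _, coefs = lars_path(X, y, method="lasso")
    norms = np.abs(coefs).sum(axis=0)
    if bound >= norms[-1]:
        return coefs[:, -1]
    k = int(np.searchsorted(norms, bound))
    # the path is linear in the L1 bound between consecutive knots
    span = norms[k] - norms[k - 1]
    frac = 0.0 if span == 0 else (bound - norms[k - 1]) / span
    return coefs[:, k - 1] + frac * (coefs[:, k] - coefs[:, k - 1])


def _fold_assignment(n_rows: int, groups: list[object], folds: int, seed: int) -> np.ndarray:
    """Fold index per row; whole provenance groups go to the same fold when possible."""
    rng = np.random.default_rng(seed)
    unique = list(dict.fromkeys(groups))
    if len(unique) >= folds:
        order = rng.permutation(len(unique))
        sizes = {g: groups.count(g) for g in unique}
        fold_load = np.zeros(folds)
        fold_of_group = {}
        for idx in order:
            g = unique[idx]
            f = int(np.argmin(fold_load))
            fold_of_group[g] = f
            fold_load[f] += sizes[g]
        return np.array([fold_of_group[g] for g in groups])
    # too few groups to fill the folds: contiguous row blocks
    assignment = np.zeros(n_rows, dtype=int)
    for f, block in enumerate(np.array_split(np.arange(n_rows), folds)):
        assignment[block] = f
    return assignment


def _path_predictions(y_tr, X_tr, X_te, grid):
    """Held-out predictions for every s on the grid from one LARS path fit."""
    ols = _ols(X_tr, y_tr)
    full_norm = np.abs(ols).sum()
    preds = np.empty((len(grid), X_te.shape[0]))
    if full_norm == 0:
        preds[:] = 0.0
        return preds
    _, _, coefs = lars_path(X_tr, y_tr, method="lasso")
    norms = np.abs(coefs).sum(axis=0)
    for a, s in enumerate(grid):
        if s == 1.0:
            beta = ols
        else:
            bound = s * full_norm
            if bound >= norms[-1]:
                beta = coefs[:, -1]
            elif bound == 0:
                beta = np.zeros(X_tr.shape[1])
            else:
                k = int(np.searchsorted(norms, bound))
                span = norms[k] - norms[k - 1]
                frac = 0.0 if span == 0 else (bound - norms[k - 1]) / span
                beta = coefs[:, k - 1] + frac * (coefs[:, k] - coefs[:, k - 1])
        preds[a] = X_te @ beta
    return preds


def cv_select_shrinkage(
    y: np.ndarray,
    X: np.ndarray,
    spec: ShrinkageSpec,
    groups: list[object] | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Choose s by K-fold cross validation.

    Returns (chosen s, mean CV error per grid value, SE per grid value).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n = y.shape[0]
    if n < spec.folds:
        raise ValueError("fewer rows than folds")
    if groups is None:
        groups = list(range(n))
    assignment = _fold_assignment(n, groups, spec.folds, spec.seed)
    fold_errors = np.full((spec.folds, len(spec.grid)), np.nan)
    for f in range(spec.folds):
        test = assignment == f
        train = ~test
        if test.sum() == 0 or train.sum() == 0:
            continue
        preds = _path_predictions(y[train], X[train], X[test], spec.grid)
        fold_errors[f] = np.mean((preds - y[test][None, :]) ** 2, axis=1)
    valid = ~np.isnan(fold_errors[:, 0])
    errors = fold_errors[valid]
    mean_err = errors.mean(axis=0)
    se = errors.std(axis=0, ddof=1) / np.sqrt(errors.shape[0])
    best = int(np.argmin(mean_err))
    if spec.rule == "min":
        chosen = spec.grid[best]
    else:
        threshold = mean_err[best] + se[best]
        ok = np.nonzero(mean_err <= threshold)[0]
        chosen = spec.grid[ok[0]]
    return float(chosen), mean_err, se


class Inferelator(BaseEstimator):
    """Sparse linear-ODE network model fit per target gene.

    Parameters
    ----------
    tau : float
        Decay time scale (minutes) used to build the ODE design.
    max_regulators : int
        Candidate-set cap P (default 10).
    cv_folds, cv_rule, s_grid, random_state
        Shrinkage selection settings (see :class:`ShrinkageSpec`).
    exclude_self_perturbation : bool
        Drop steady-state rows in which the target itself is clamped.

    Attributes
    ----------
    coef_ : ndarray of shape (n_genes, n_genes)
        Kinetic weight matrix beta; rows = targets, columns = regulators.
    shrinkage_ : ndarray of shape (n_genes,)
        Chosen s per target (nan for targets with no candidates).
    candidates_ : list of list of int
        Candidate regulator set R_i per target.
    """

    def __init__(
        self,
        tau: float = DEFAULT_TAU,
        max_regulators: int = DEFAULT_MAX_REGULATORS,
        cv_folds: int = 10,
        cv_rule: str = "1se",
        s_grid: np.ndarray | None = None,
        random_state: int = 0,
        exclude_self_perturbation: bool = True,
    ):
        self.tau = tau
        self.max_regulators = max_regulators
        self.cv_folds = cv_folds
        self.cv_rule = cv_rule
        self.s_grid = s_grid
        self.random_state = random_state
        self.exclude_self_perturbation = exclude_self_perturbation

    def fit(self, X: ExpressionDataset, y: np.ndarray) -> "Inferelator":
        """Fit per-target models; ``y`` is the confidence matrix supplying candidates."""
        dataset = X
        m2 = np.asarray(y, dtype=float)
        if m2.shape != (dataset.n_genes, dataset.n_genes):
            raise ValueError("confidence matrix shape differs from dataset gene count")
        pairs = build_dynamic_pairs(dataset, tau=self.tau)
        grid = DEFAULT_S_GRID.copy() if self.s_grid is None else np.asarray(self.s_grid, float)
        n = dataset.n_genes
        self.coef_ = np.zeros((n, n))
        self.shrinkage_ = np.full(n, np.nan)
        self.candidates_ = []
        self.design_pairs_ = pairs
        for i in range(n):
            cand = select_candidates(m2, i, self.max_regulators)
            self.candidates_.append(cand)
            if not cand:
                continue
            mask = pairs.rows_for_target(i, self.exclude_self_perturbation)
            yi = pairs.response[mask, i]
            Xi = pairs.explanatory[np.ix_(mask, cand)]
            groups = [
                (t.kind, t.experiment) if t.kind == "ts" else ("ss", t.experiment)
                for t, keep in zip(pairs.tags, mask)
                if keep
            ]
            spec = ShrinkageSpec(
                grid=grid,
                folds=self.cv_folds,
                seed=self.random_state * 100003 + i,
                rule=self.cv_rule,
            )
            s, _, _ = cv_select_shrinkage(yi, Xi, spec, groups)
            self.shrinkage_[i] = s
            beta = lasso_path_coef(yi, Xi, s)
            self.coef_[i, cand] = beta
            logger.debug("target %d: |R|=%d, s=%.2f, nnz=%d", i, len(cand), s, np.count_nonzero(beta))
        return self

    def predict_response(self, pairs: DesignPairs | None = None) -> np.ndarray:
        """Model-implied response matrix X @ beta.T on the fitted (or given) design."""
        pairs = pairs if pairs is not None else self.design_pairs_
        return pairs.explanatory @ self.coef_.T


def fit_all_targets(
    dataset: ExpressionDataset,
    m2: np.ndarray,
    tau: float = DEFAULT_TAU,
    max_regulators: int = DEFAULT_MAX_REGULATORS,
    spec: ShrinkageSpec | None = None,
    exclude_self_perturbation: bool = True,
) -> Inferelator:
    """Functional wrapper over :class:`Inferelator`."""
    spec = spec or ShrinkageSpec()
    est = Inferelator(
        tau=tau,
        max_regulators=max_regulators,
        cv_folds=spec.folds,
        cv_rule=spec.rule,
        s_grid=spec.grid,
        random_state=spec.seed,
        exclude_self_perturbation=exclude_self_perturbation,
    )
    return est.fit(dataset, m2)
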