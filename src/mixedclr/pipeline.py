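"""End-to-end network inference pipeline.

Three stages: (1) score every ordered gene pair with a CLR variant
(mixed-CLR by default), (2) send the least perturbation-responsive pairs
to the list tail using knock-out/knock-down steady states, (3) fit a
sparse ODE model per target on the surviving candidates and fold its
support back into the ranking by rank substitution.  Alternative modes
reproduce each single-method baseline on the same data.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import __version__
from .clr import CLRScorer
from .filtration import KnockoutFilter
from .io import ExpressionDataset, RankedEdgeList, write_predictions
from .ranking import final_scores, rank_by_weights, to_ranked_list, weights_to_confidences
from .regression import Inferelator

__all__ = ["GRNPipeline", "run_pipeline"]

logger = logging.getLogger(__name__)

MODES = ("pipeline", "mixed-clr-only", "clr-only", "dynamic-clr-only", "inferelator-only")
_MODE_VARIANT = {
    "pipeline": None,  # taken from clr_variant
    "mixed-clr-only": "mixed",
    "clr-only": "static",
    "dynamic-clr-only": "dynamic",
    "inferelator-only": "correlation",
}


class GRNPipeline(BaseEstimator):
    """Fit the full three-stage pipeline (or a single-method baseline).

    Parameters
    ----------
    mode : str
        'pipeline' (CLR variant + filtration + regression) or one of the
        single-method baselines.  'inferelator-only' selects candidates
        from the |dynamic correlation| matrix and ranks by |beta|.
    clr_variant : {'mixed', 'static', 'dynamic'}
        Stage-one scorer used in 'pipeline' mode.
    theta, filter_fraction
        Filtration cutoff, or the fraction of ordered pairs to filter
        (default about one third); ``no_filter=True`` skips stage two.
    use : {'all', 'ko', 'kd', 'ts'}
        Data partition fed to every stage.

    Attributes
    ----------
    m1_, m2_, m3_ : ndarray
        Confidence matrices after each stage (aliased where stages are skipped).
    ranking_ : RankedEdgeList
    """

    def __init__(
        self,
        mode: str = "pipeline",
        clr_variant: str = "mixed",
        bins: int = 10,
        order: int = 3,
        tau: float = 10.0,
        theta: float | None = None,
        filter_fraction: float | None = None,
        no_filter: bool = False,
        max_regulators: int = 10,
        cv_folds: int = 10,
        cv_rule: str = "1se",
        random_state: int = 0,
        use: str = "all",
    ):
        self.mode = mode
        self.clr_variant = clr_variant
        self.bins = bins
        self.order = order
        self.tau = tau
        self.theta = theta
        self.filter_fraction = filter_fraction
        self.no_filter = no_filter
        self.max_regulators = max_regulators
        self.cv_folds = cv_folds
        self.cv_rule = cv_rule
        self.random_state = random_state
        self.use = use

    def fit(self, X: ExpressionDataset, y=None) -> "GRNPipeline":
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        dataset = X.restrict(self.use)
        variant = _MODE_VARIANT[self.mode] or self.clr_variant
        scorer = CLRScorer(variant=variant, bins=self.bins, order=self.order, tau=self.tau)
        scorer.fit(dataset)
        self.scorer_ = scorer
        self.m1_ = scorer.scores_
        logger.info("stage 1 (%s): scored %d pairs", variant, self.m1_.size - len(self.m1_))

        run_filter = self.mode == "pipeline" and not self.no_filter and self.theta != 0
        if run_filter:
            filt = KnockoutFilter(theta=self.theta, filter_fraction=self.filter_fraction)
            filt.fit(dataset)
            self.filter_ = filt
            self.m2_ = filt.transform(self.m1_)
            logger.info("stage 2: filtered %d pairs (theta=%.4g)", filt.n_filtered_, filt.theta_)
        else:
            self.filter_ = None
            self.m2_ = self.m1_.copy()

        if self.mode in ("pipeline", "inferelator-only"):
            inferelator = Inferelator(
                tau=self.tau,
                max_regulators=self.max_regulators,
                cv_folds=self.cv_folds,
                cv_rule=self.cv_rule,
                random_state=self.random_state,
            )
            inferelator.fit(dataset, self.m2_)
            self.inferelator_ = inferelator
            if self.mode == "inferelator-only":
                self.m3_ = np.abs(inferelator.coef_)
                self.ranking_ = rank_by_weights(inferelator.coef_)
            else:
                confidences = weights_to_confidences(inferelator.coef_, self.m2_)
                self.m3_ = final_scores(self.m2_, confidences)
                self.ranking_ = to_ranked_list(self.m3_)
            sizes = [len(c) for c in inferelator.candidates_]
            logger.info(
                "stage 3: mean candidate-set size %.1f, mean s %.2f",
                float(np.mean(sizes)),
                float(np.nanmean(inferelator.shrinkage_)),
            )
        else:
            self.inferelator_ = None
            self.m3_ = self.m2_
            self.ranking_ = to_ranked_list(self.m3_)
        return self

    def manifest(self) -> dict:
        """All parameters needed to reproduce this run."""
        info = {"package_version": __version__, **self.get_params()}
        if getattr(self, "filter_", None) is not None:
            info["theta_applied"] = self.filter_.theta_
            info["n_filtered"] = self.filter_.n_filtered_
        return info


def run_pipeline(
    dataset: ExpressionDataset,
    out_dir: str | Path | None = None,
    **params,
) -> RankedEdgeList:
    """Fit :class:`GRNPipeline` and optionally write all run artifacts.

    Artifacts: stage matrices (m1/m2/m3 as TSV), the prediction list and
    a JSON manifest of parameters.
    """
    pipe = GRNPipeline(**params).fit(dataset)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("m1_", "m2_", "m3_"):
            np.savetxt(out_dir / f"{name.rstrip('_')}.tsv", getattr(pipe, name), delimiter="\t")
        write_predictions(out_dir / "predictions.tsv", pipe.ranking_)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(pipe.manifest(), fh, indent=2, default=str)
    return pipe.ranking_
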