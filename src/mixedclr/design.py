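"""ODE-derived response and time-lagged explanatory variables.

The transcription model is a linear additive ODE for each target i:

    dx_i/dt = -x_i / tau + sum_j beta_ij x_j

with tau the first-order decay time scale (minutes).  Within each
time-series experiment, a forward finite difference over consecutive
observations turns the left-hand side into a response variable

    y_i[k] = (x_i(t_{k+1}) - x_i(t_k)) / dt_k + x_i(t_k) / tau

paired with explanatory variables chi_j[k] = x_j(t_k), which are
time-lagged by one observation relative to the response.  At steady
state the derivative vanishes, so each steady-state experiment
contributes y_i = x_i / tau against chi_j = x_j.  Stacking time-series
transitions and steady-state experiments gives one shared row schema
that all dynamic scoring and regression steps consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionDataset

__all__ = ["RowTag", "DesignPairs", "build_response", "build_explanatory", "build_dynamic_pairs"]

DEFAULT_TAU = 10.0
"""Default mRNA decay time scale in minutes (half-life tau * ln 2 ~ 6.9 min)."""


@dataclass(frozen=True)
class RowTag:
    """Provenance of one design row.

    kind: 'ts' (a transition within a time-series experiment) or 'ss'.
    experiment: time-series experiment index, or steady-state row index.
    transition: index of the transition within the experiment (ts only).
    perturbed_gene: gene clamped by the steady-state intervention, if any.
    """

    kind: str
    experiment: int
    transition: int | None = None
    perturbed_gene: int | None = None


@dataclass
class DesignPairs:
    """Aligned response (Y) and time-lagged explanatory (X) matrices.

    Row r of ``explanatory`` was observed one time step before (time
    series) or at (steady state) the observation defining row r of
    ``response``.  Column order follows the dataset's gene order.
    """

    response: np.ndarray  # R x N, column i = y_i
    explanatory: np.ndarray  # R x N, column j = chi_j
    tau: float
    tags: list[RowTag]

    def __post_init__(self) -> None:
        if self.response.shape != self.explanatory.shape:
            raise ValueError("response/explanatory shape mismatch")
        if len(self.tags) != self.response.shape[0]:
            raise ValueError("one provenance tag per row required")

    @property
    def n_rows(self) -> int:
        return self.response.shape[0]

    @property
    def n_genes(self) -> int:
        return self.response.shape[1]

    def rows_for_target(self, target: int, exclude_self_perturbation: bool = True) -> np.ndarray:
        """Row mask for fitting target ``target``.

        When the target itself is the clamped gene of a steady-state
        experiment its level is set by the intervention, not by the
        transcription model, so those rows are dropped by default.
        """
        mask = np.ones(self.n_rows, dtype=bool)
        if exclude_self_perturbation:
            for r, tag in enumerate(self.tags):
                if tag.perturbed_gene == target:
                    mask[r] = False
        return mask


def _check_tau(tau: float) -> float:
    tau = float(tau)
    if not tau > 0:
        raise ValueError("tau must be > 0")
    return tau


def build_dynamic_pairs(dataset: ExpressionDataset, tau: float = DEFAULT_TAU) -> DesignPairs:
    """Assemble response and explanatory matrices for every gene at once."""
    tau = _check_tau(tau)
    y_blocks: list[np.ndarray] = []
    x_blocks: list[np.ndarray] = []
    tags: list[RowTag] = []
    for e, ts in enumerate(dataset.time_series):
        if ts.n_times < 2:
            continue
        dt = np.diff(ts.times)[:, None]
        earlier = ts.values[:-1]
        later = ts.values[1:]
        y_blocks.append((later - earlier) / dt + earlier / tau)
        x_blocks.append(earlier)
        tags.extend(RowTag("ts", e, transition=k) for k in range(ts.n_times - 1))
    ss = dataset.steady_state_matrix()
    if ss.shape[0]:
        y_blocks.append(ss / tau)
        x_blocks.append(ss)
        tags.extend(
            RowTag("ss", k, perturbed_gene=g)
            for k, g in enumerate(dataset.steady_state_perturbed_genes())
        )
    if not y_blocks:
        raise ValueError("dataset has neither time-series nor steady-state observations")
    return DesignPairs(
        response=np.vstack(y_blocks),
        explanatory=np.vstack(x_blocks),
        tau=tau,
        tags=tags,
    )


def build_response(dataset: ExpressionDataset, target: int, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Response vector y_i for one target (time-series transitions, then steady states)."""
    if not (0 <= target < dataset.n_genes):
        raise IndexError("target index out of range")
    return build_dynamic_pairs(dataset, tau).response[:, target].copy()


def build_explanatory(dataset: ExpressionDataset, regulator: int, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Time-lagged explanatory vector chi_j, row-aligned with :func:`build_response`."""
    if not (0 <= regulator < dataset.n_genes):
        raise IndexError("regulator index out of range")
    return build_dynamic_pairs(dataset, tau).explanatory[:, regulator].copy()
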