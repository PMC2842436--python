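"""Synthetic gene-network benchmarks: ground-truth topology plus simulated data.

Networks are sparse directed graphs with signed kinetic weights; expression
follows the same linear additive ODE the inference pipeline assumes,

    dx_i/dt = b_i - x_i / tau + sum_j A[i, j] f(x_j),

with f(x) = x (default) or an optional saturating Hill response that
introduces model mismatch.  The simulated experiment designs mirror the
DREAM-style layout: a wild-type steady state, one knock-out (clamp to 0)
and one knock-down (clamp to half wild type) steady state per gene, and
perturbed time courses sampled at equal intervals.  All observations are
rescaled into [0, 1] by the global maximum and optionally corrupted with
additive Gaussian noise (clipped back into [0, 1]).  Every operation is
reproducible from its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .io import (
    ExpressionDataset,
    GoldStandard,
    TimeSeriesExperiment,
    save_dataset,
    write_gold_standard,
)

__all__ = ["SyntheticNetwork", "generate_network", "simulate_dataset", "make_benchmark_suite"]

logger = logging.getLogger(__name__)

DEFAULT_TAU = 10.0
DEFAULT_NOISE_SD = 0.025
DEFAULT_N_TS = 23
DEFAULT_N_TIMES = 21
DEFAULT_DT = 20.0


@dataclass
class SyntheticNetwork:
    """Ground-truth network: signed kinetic weights, basal rates, decay time scale."""

    weights: np.ndarray  # [i, j] = effect of regulator j on target i
    basal: np.ndarray
    tau: float
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    @property
    def genes(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_genes)]

    def edges(self) -> list[tuple[int, int]]:
        """(regulator, target) pairs with nonzero weight."""
        targets, regulators = np.nonzero(self.weights)
        return sorted(zip(regulators.tolist(), targets.tolist()))

    def gold_standard(self) -> GoldStandard:
        return GoldStandard(n_genes=self.n_genes, edges=frozenset(self.edges()))

    def in_degrees(self) -> np.ndarray:
        return (self.weights != 0).sum(axis=1)

    def out_degrees(self) -> np.ndarray:
        return (self.weights != 0).sum(axis=0)

    def wildtype_state(self) -> np.ndarray:
        """Noise-free fixed point of the linear kinetics."""
        n = self.n_genes
        return np.linalg.solve(np.eye(n) / self.tau - self.weights, self.basal)


def _draw_topology(
    rng: np.random.Generator,
    n_genes: int,
    n_edges: int,
    indegree_cap: int | None,
    mode: str,
    regulator_pool: int | None,
    target_indegree: int | None,
) -> np.ndarray:
    adj = np.zeros((n_genes, n_genes), dtype=bool)
    pool = np.arange(n_genes if regulator_pool is None else regulator_pool)
    if mode == "hub":
        # heavy-tailed regulator choice: a few genes accumulate many targets
        raw = 1.0 / np.arange(1, len(pool) + 1)
        reg_p = raw[rng.permutation(len(pool))]
        reg_p /= reg_p.sum()
    elif mode == "random":
        reg_p = np.full(len(pool), 1.0 / len(pool))
    else:
        raise ValueError(f"unknown network mode {mode!r}")

    if target_indegree is not None:
        if indegree_cap is not None and target_indegree > indegree_cap:
            raise ValueError("target_indegree exceeds indegree_cap")
        if target_indegree > len(pool) - 1:
            raise ValueError("target_indegree infeasible for regulator pool size")
        for i in range(n_genes):
            choices = pool[pool != i]
            p = reg_p[pool != i]
            regs = rng.choice(choices, size=target_indegree, replace=False, p=p / p.sum())
            adj[i, regs] = True
        return adj

    cap = indegree_cap if indegree_cap is not None else n_genes - 1
    if n_edges > n_genes * min(cap, len(pool) - 1):
        raise ValueError("requested edge count infeasible under degree constraints")
    attempts = 0
    while adj.sum() < n_edges:
        attempts += 1
        if attempts > 200 * n_edges:
            raise ValueError("could not satisfy degree constraints")
        j = int(rng.choice(pool, p=reg_p))
        i = int(rng.integers(n_genes))
        if i == j or adj[i, j] or adj[i].sum() >= cap:
            continue
        adj[i, j] = True
    return adj


def generate_network(
    n_genes: int,
    density: float = 2.0,
    indegree_cap: int | None = None,
    seed: int = 0,
    mode: str = "random",
    regulator_pool: int | None = None,
    target_indegree: int | None = None,
    tau: float = DEFAULT_TAU,
    activation_prob: float = 0.7,
) -> SyntheticNetwork:
    """Sample a sparse signed network with a stable, positive fixed point.

    ``density`` is the mean number of edges per gene (ignored when
    ``target_indegree`` fixes every in-degree).  ``mode='hub'`` draws
    regulators with heavy-tailed propensities; ``regulator_pool`` limits
    which genes may act as regulators.  Weight magnitudes are damped (and
    logged) until the linear kinetics are stable with a strictly positive
    steady state.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if density <= 0:
        raise ValueError("density must be > 0")
    rng = np.random.default_rng(seed)
    n_edges = max(1, int(round(density * n_genes)))
    adj = _draw_topology(rng, n_genes, n_edges, indegree_cap, mode, regulator_pool, target_indegree)
    signs = np.where(rng.random(adj.shape) < activation_prob, 1.0, -1.0)
    magnitude = rng.uniform(0.015, 0.045, size=adj.shape)
    weights = np.where(adj, signs * magnitude, 0.0)
    basal = rng.uniform(0.03, 0.08, size=n_genes)
    for damp_round in range(60):
        system = weights - np.eye(n_genes) / tau
        stable = np.max(np.linalg.eigvals(system).real) < -1e-4
        if stable:
            state = np.linalg.solve(-system, basal)
            if np.all(state > 1e-3):
                if damp_round:
                    logger.info("damped weights %d time(s) for stability", damp_round)
                return SyntheticNetwork(
                    weights=weights,
                    basal=basal,
                    tau=tau,
                    seed=seed,
                    params={
                        "density": density,
                        "mode": mode,
                        "indegree_cap": indegree_cap,
                        "regulator_pool": regulator_pool,
                        "target_indegree": target_indegree,
                    },
                )
        weights = weights * 0.7
    raise ValueError("could not stabilise network kinetics")


def _hill(x: np.ndarray) -> np.ndarray:
    return x / (0.5 + np.abs(x))


def _steady_state_clamped(
    network: SyntheticNetwork, clamp_gene: int, clamp_value: float, kinetics: str
) -> np.ndarray:
    n = network.n_genes
    free = np.array([g for g in range(n) if g != clamp_gene])
    if kinetics == "linear":
        system = np.eye(n) / network.tau - network.weights
        rhs = network.basal[free] + network.weights[free, clamp_gene] * clamp_value
        x_free = np.linalg.solve(system[np.ix_(free, free)], rhs)
        state = np.empty(n)
        state[free] = x_free
        state[clamp_gene] = clamp_value
        return state
    # saturating kinetics: relax the clamped ODE numerically
    def deriv(_t, x):
        dx = network.basal - x / network.tau + network.weights @ _hill(x)
        dx[clamp_gene] = 0.0
        return dx

    x0 = network.wildtype_state()
    x0[clamp_gene] = clamp_value
    sol = solve_ivp(deriv, (0.0, 50 * network.tau), x0, method="LSODA", rtol=1e-8, atol=1e-10)
    return sol.y[:, -1]


def _wildtype(network: SyntheticNetwork, kinetics: str) -> np.ndarray:
    if kinetics == "linear":
        return network.wildtype_state()

    def deriv(_t, x):
        return network.basal - x / network.tau + network.weights @ _hill(x)

    sol = solve_ivp(
        deriv, (0.0, 50 * network.tau), network.wildtype_state(), method="LSODA",
        rtol=1e-8, atol=1e-10,
    )
    return sol.y[:, -1]


def _trajectory(
    network: SyntheticNetwork, x0: np.ndarray, n_times: int, dt: float, kinetics: str
) -> np.ndarray:
    n = network.n_genes
    if kinetics == "linear":
        system = network.weights - np.eye(n) / network.tau
        fixed = network.wildtype_state()
        step = expm(system * dt)
        traj = np.empty((n_times, n))
        traj[0] = x0
        for k in range(1, n_times):
            traj[k] = fixed + step @ (traj[k - 1] - fixed)
        return traj

    def deriv(_t, x):
        return network.basal - x / network.tau + network.weights @ _hill(x)

    times = np.arange(n_times) * dt
    sol = solve_ivp(deriv, (0.0, times[-1]), x0, t_eval=times, method="LSODA", rtol=1e-8, atol=1e-10)
    return sol.y.T


def simulate_dataset(
    network: SyntheticNetwork,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_ts: int = DEFAULT_N_TS,
    n_times: int = DEFAULT_N_TIMES,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    kinetics: str = "linear",
    ts_perturbation: float = 0.75,
) -> ExpressionDataset:
    """Simulate wild-type, per-gene KO/KD steady states and perturbed time courses.

    ``ts_perturbation`` a draws each time course's initial condition as
    WT * Uniform(1 - a, 1 + a) per gene (0 starts every course at the
    fixed point).  Observation noise is additive Gaussian with standard
    deviation ``noise_sd`` on the rescaled [0, 1] scale.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if kinetics not in {"linear", "hill"}:
        raise ValueError("kinetics must be 'linear' or 'hill'")
    rng = np.random.default_rng(seed)
    n = network.n_genes
    wt = _wildtype(network, kinetics)
    ko = np.vstack(
        [_steady_state_clamped(network, g, 0.0, kinetics) for g in range(n)]
    )
    kd = np.vstack(
        [_steady_state_clamped(network, g, wt[g] / 2.0, kinetics) for g in range(n)]
    )
    times = np.arange(n_times) * dt
    trajectories = []
    for _ in range(n_ts):
        factors = rng.uniform(1.0 - ts_perturbation, 1.0 + ts_perturbation, size=n)
        x0 = np.clip(wt * factors, 0.0, None)
        trajectories.append(_trajectory(network, x0, n_times, dt, kinetics))

    blocks = [wt[None, :], ko, kd, *trajectories]
    scale = max(float(np.max(np.vstack(blocks))), 1e-12)

    def observe(block: np.ndarray) -> np.ndarray:
        scaled = np.clip(block / scale, 0.0, 1.0)
        if noise_sd > 0:
            scaled = scaled + rng.normal(0.0, noise_sd, size=scaled.shape)
        return np.clip(scaled, 0.0, 1.0)

    return ExpressionDataset(
        genes=network.genes,
        time_series=[
            TimeSeriesExperiment(times=times.copy(), values=observe(traj))
            for traj in trajectories
        ],
        wildtype=observe(wt[None, :])[0],
        knockout=observe(ko),
        knockdown=observe(kd),
    )


def make_benchmark_suite(
    n_networks: int = 5,
    n_genes: int = 50,
    density: float = 2.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    out_dir: str | Path | None = None,
    **simulate_kwargs,
) -> list[tuple[SyntheticNetwork, ExpressionDataset, GoldStandard]]:
    """Generate an ensemble of (network, dataset, gold standard) triples.

    Per-network seeds are derived deterministically from ``seed``.  With
    ``out_dir`` the datasets and gold standards are also written in the
    tab-delimited dialect, one subdirectory per network.
    """
    suite = []
    for k in range(n_networks):
        net_seed = (seed * 1009 + k) % (2**31 - 1)
        network = generate_network(n_genes, density=density, seed=net_seed)
        dataset = simulate_dataset(
            network, noise_sd=noise_sd, seed=net_seed + 1, **simulate_kwargs
        )
        gold = network.gold_standard()
        if out_dir is not None:
            directory = Path(out_dir) / f"network_{k + 1}"
            save_dataset(directory, dataset)
            write_gold_standard(directory / "goldstandard.tsv", gold)
        suite.append((network, dataset, gold))
    return suite
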