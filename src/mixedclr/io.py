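"""Readers and writers for DREAM-style expression tables, gold standards and predictions.

All files are tab-delimited text.  Gene identifiers are ``G1`` ... ``GN``
(1-based) in files; internally every matrix is indexed 0-based in the order
given by :attr:`ExpressionDataset.genes`, which is the single source of truth
for gene order throughout the package.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TimeSeriesExperiment",
    "ExpressionDataset",
    "GoldStandard",
    "RankedEdgeList",
    "read_steady_state_table",
    "read_time_series",
    "read_gold_standard",
    "write_steady_state_table",
    "write_time_series",
    "write_gold_standard",
    "write_predictions",
    "read_predictions",
    "load_dataset",
    "save_dataset",
]


class ParseError(ValueError):
    """Raised when a DREAM-style table violates its format contract."""


@dataclass
class TimeSeriesExperiment:
    """One perturbation time course: observation times (minutes) and a T x N matrix."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.times.ndim != 1 or len(self.times) != self.values.shape[0]:
            raise ValueError("times and expression matrix row counts differ")
        if len(self.times) < 2:
            raise ValueError("a time-series experiment needs >= 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")

    @property
    def n_times(self) -> int:
        return len(self.times)


@dataclass
class ExpressionDataset:
    """Expression observations for one network: time series plus steady states.

    ``knockout`` row g is the steady state with gene g forced to ~0
    (null mutant); ``knockdown`` row g has gene g forced to ~half its
    wild-type level (heterozygote).  Any block may be absent (``None``).
    """

    genes: list[str]
    time_series: list[TimeSeriesExperiment] = field(default_factory=list)
    wildtype: np.ndarray | None = None
    knockout: np.ndarray | None = None
    knockdown: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.n_genes
        if n == 0:
            raise ValueError("dataset needs at least one gene")
        for ts in self.time_series:
            if ts.values.shape[1] != n:
                raise ValueError("time-series gene count differs from gene list")
        for name in ("wildtype", "knockout", "knockdown"):
            block = getattr(self, name)
            if block is None:
                continue
            block = np.asarray(block, dtype=float)
            if name == "wildtype":
                block = block.reshape(-1)
                if block.shape != (n,):
                    raise ValueError("wildtype must be a length-N vector")
            else:
                if block.shape != (n, n):
                    raise ValueError(f"{name} must be an N x N matrix")
            setattr(self, name, block)
        self._validate_values()

    def _validate_values(self) -> None:
        for block in self._iter_blocks():
            if not np.all(np.isfinite(block)):
                raise ValueError("expression values must be finite")
            if np.any(block < 0):
                raise ValueError("expression values must be >= 0")
            if np.any(block > 1.0 + 1e-9):
                warnings.warn(
                    "expression values outside [0, 1]; no rescaling is applied",
                    stacklevel=3,
                )

    def _iter_blocks(self):
        for ts in self.time_series:
            yield ts.values
        for name in ("wildtype", "knockout", "knockdown"):
            block = getattr(self, name)
            if block is not None:
                yield block

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def has_time_series(self) -> bool:
        return len(self.time_series) > 0

    @property
    def has_knockout(self) -> bool:
        return self.knockout is not None

    @property
    def has_knockdown(self) -> bool:
        return self.knockdown is not None

    def steady_state_matrix(self) -> np.ndarray:
        """All steady-state experiments stacked as an S x N matrix (WT, KO rows, KD rows)."""
        rows = []
        if self.wildtype is not None:
            rows.append(self.wildtype[None, :])
        if self.knockout is not None:
            rows.append(self.knockout)
        if self.knockdown is not None:
            rows.append(self.knockdown)
        if not rows:
            return np.empty((0, self.n_genes))
        return np.vstack(rows)

    def steady_state_perturbed_genes(self) -> list[int | None]:
        """Which gene is clamped in each steady-state row (None for wild type)."""
        tags: list[int | None] = []
        if self.wildtype is not None:
            tags.append(None)
        if self.knockout is not None:
            tags.extend(range(self.n_genes))
        if self.knockdown is not None:
            tags.extend(range(self.n_genes))
        return tags

    def profile_matrix(self) -> np.ndarray:
        """Per-gene expression profiles: all time-series rows then all steady states.

        This is the sample-by-gene matrix from which static mutual
        information between gene pairs is estimated.
        """
        rows = [ts.values for ts in self.time_series]
        rows.append(self.steady_state_matrix())
        mat = np.vstack([r for r in rows if r.size]) if rows else np.empty((0, self.n_genes))
        if mat.shape[0] == 0:
            raise ValueError("dataset has no observations")
        return mat

    def restrict(self, use: str) -> "ExpressionDataset":
        """Keep only one data partition: 'ko', 'kd', 'ts' or 'all'.

        The wild-type experiment accompanies the 'ko' and 'kd' partitions
        (it is the reference the perturbations are measured against).
        """
        if use == "all":
            return self
        if use == "ko":
            if self.knockout is None:
                raise ValueError("knock-out block is not available")
            return replace(self, time_series=[], knockdown=None)
        if use == "kd":
            if self.knockdown is None:
                raise ValueError("knock-down block is not available")
            return replace(self, time_series=[], knockout=None)
        if use == "ts":
            if not self.time_series:
                raise ValueError("time-series block is not available")
            return replace(self, wildtype=None, knockout=None, knockdown=None)
        raise ValueError(f"unknown data partition {use!r}")


@dataclass(frozen=True)
class GoldStandard:
    """True directed edges (regulator, target), 0-based; all other ordered pairs are negatives."""

    n_genes: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for j, i in self.edges:
            if j == i:
                raise ValueError("gold standard contains a self-edge")
            if not (0 <= j < self.n_genes and 0 <= i < self.n_genes):
                raise ValueError("gold-standard edge endpoint out of range")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Boolean matrix, rows = targets, columns = regulators."""
        adj = np.zeros((self.n_genes, self.n_genes), dtype=bool)
        for j, i in self.edges:
            adj[i, j] = True
        return adj


@dataclass
class RankedEdgeList:
    """All N(N-1) ordered pairs (regulator, target, score), descending score."""

    n_genes: int
    edges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        seen = set()
        prev = np.inf
        for j, i, score in self.edges:
            if j == i:
                raise ValueError(f"self-edge G{j + 1}->G{i + 1} in ranked list")
            if (j, i) in seen:
                raise ValueError(f"duplicate ordered pair G{j + 1}->G{i + 1}")
            seen.add((j, i))
            if score > prev + 1e-12:
                raise ValueError("ranked list scores are not descending")
            prev = score
        expected = self.n_genes * (self.n_genes - 1)
        if len(self.edges) != expected:
            raise ValueError(
                f"ranked list must cover all {expected} ordered pairs, got {len(self.edges)}"
            )

    def ranks(self) -> dict[tuple[int, int], int]:
        """1-based rank of every ordered pair."""
        return {(j, i): r + 1 for r, (j, i, _) in enumerate(self.edges)}


_GENE_RE = re.compile(r"^G(\d+)$")


def _gene_index(token: str, n_genes: int, path, lineno: int) -> int:
    m = _GENE_RE.match(token.strip())
    if not m:
        raise ParseError(f"{path}:{lineno}: bad gene identifier {token!r}")
    idx = int(m.group(1)) - 1
    if not (0 <= idx < n_genes):
        raise ParseError(f"{path}:{lineno}: gene index out of range: {token}")
    return idx


def _parse_cell(cell: str, path, lineno: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-numeric cell {cell!r}") from None


def read_steady_state_table(path) -> tuple[np.ndarray, list[str]]:
    """Read a steady-state table: header of gene names, one experiment per row."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    genes = lines[0].split("\t")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(genes):
            raise ParseError(
                f"{path}:{lineno}: expected {len(genes)} columns, got {len(cells)}"
            )
        rows.append([_parse_cell(c, path, lineno) for c in cells])
    mat = np.array(rows, dtype=float) if rows else np.empty((0, len(genes)))
    return mat, genes


def write_steady_state_table(path, matrix: np.ndarray, genes: list[str]) -> None:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    with open(path, "w") as fh:
        fh.write("\t".join(genes) + "\n")
        for row in matrix:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_time_series(path) -> tuple[list[TimeSeriesExperiment], list[str]]:
    """Read time-series experiments; blocks split on blank lines or time resets."""
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    header = None
    genes: list[str] = []
    blocks: list[tuple[list[float], list[list[float]]]] = []
    times: list[float] = []
    values: list[list[float]] = []

    def flush():
        nonlocal times, values
        if times:
            blocks.append((times, values))
        times, values = [], []

    for lineno, ln in enumerate(raw, start=1):
        if not ln.strip():
            flush()
            continue
        cells = ln.split("\t")
        if cells[0].strip().lower() == "time":
            if header is not None and cells[1:] != header[1:]:
                raise ParseError(f"{path}:{lineno}: inconsistent gene header")
            if header is None:
                header = cells
                genes = cells[1:]
            flush()
            continue
        if header is None:
            raise ParseError(f"{path}:{lineno}: missing 'Time' header")
        if len(cells) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        t = _parse_cell(cells[0], path, lineno)
        row = [_parse_cell(c, path, lineno) for c in cells[1:]]
        if times and t <= times[-1]:
            # time reset starts a new perturbation experiment
            flush()
        times.append(t)
        values.append(row)
    flush()
    if header is None:
        raise ParseError(f"{path}: no 'Time' header found")
    experiments = [
        TimeSeriesExperiment(np.array(t), np.array(v)) for t, v in blocks
    ]
    return experiments, genes


def write_time_series(path, experiments: list[TimeSeriesExperiment], genes: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("Time\t" + "\t".join(genes) + "\n")
        for k, ts in enumerate(experiments):
            if k:
                fh.write("\n")
            for t, row in zip(ts.times, ts.values):
                fh.write(f"{t:.10g}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_gold_standard(path, n_genes: int) -> GoldStandard:
    """Read 'G<j>\\tG<i>\\t1' lines (regulator, target); absent pairs are negatives."""
    edges = set()
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            cells = ln.split("\t")
            if len(cells) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
            j = _gene_index(cells[0], n_genes, path, lineno)
            i = _gene_index(cells[1], n_genes, path, lineno)
            label = cells[2].strip() if len(cells) > 2 else "1"
            if label == "1":
                edges.add((j, i))
            elif label != "0":
                raise ParseError(f"{path}:{lineno}: bad label {label!r}")
    return GoldStandard(n_genes=n_genes, edges=frozenset(edges))


def write_gold_standard(path, gold: GoldStandard) -> None:
    with open(path, "w") as fh:
        for j, i in sorted(gold.edges):
            fh.write(f"G{j + 1}\tG{i + 1}\t1\n")


def write_predictions(path, ranked: RankedEdgeList) -> None:
    """Write a prediction list, one 'G<regulator>\\tG<target>\\t<score>' line per pair."""
    with open(path, "w") as fh:
        for j, i, score in ranked.edges:
            fh.write(f"G{j + 1}\tG{i + 1}\t{score:.10f}\n")


def read_predictions(path, n_genes: int) -> RankedEdgeList:
    edges = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            cells = ln.split("\t")
            if len(cells) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            j = _gene_index(cells[0], n_genes, path, lineno)
            i = _gene_index(cells[1], n_genes, path, lineno)
            edges.append((j, i, _parse_cell(cells[2], path, lineno)))
    return RankedEdgeList(n_genes=n_genes, edges=edges)


# Directory-level convenience: one file per data block, the layout the
# synthetic benchmark writer emits and the CLI consumes.
_FILES = {
    "wildtype": "wildtype.tsv",
    "knockout": "knockouts.tsv",
    "knockdown": "knockdowns.tsv",
    "time_series": "timeseries.tsv",
}


def save_dataset(directory, dataset: ExpressionDataset) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if dataset.wildtype is not None:
        write_steady_state_table(directory / _FILES["wildtype"], dataset.wildtype, dataset.genes)
    if dataset.knockout is not None:
        write_steady_state_table(directory / _FILES["knockout"], dataset.knockout, dataset.genes)
    if dataset.knockdown is not None:
        write_steady_state_table(directory / _FILES["knockdown"], dataset.knockdown, dataset.genes)
    if dataset.time_series:
        write_time_series(directory / _FILES["time_series"], dataset.time_series, dataset.genes)


def load_dataset(directory) -> ExpressionDataset:
    from pathlib import Path

    directory = Path(directory)
    genes: list[str] | None = None
    blocks: dict[str, object] = {}
    for key, fname in _FILES.items():
        path = directory / fname
        if not path.exists():
            continue
        if key == "time_series":
            experiments, g = read_time_series(path)
            blocks["time_series"] = experiments
        else:
            mat, g = read_steady_state_table(path)
            blocks[key] = mat[0] if key == "wildtype" else mat
        if genes is None:
            genes = g
        elif g != genes:
            raise ParseError(f"{path}: gene header differs between files")
    if genes is None:
        raise ParseError(f"{directory}: no expression tables found")
    return ExpressionDataset(genes=genes, **blocks)
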