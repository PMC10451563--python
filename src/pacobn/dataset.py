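"""Signal tables and their discretization.

Continuous biological signals (fMRI BOLD series, flow-cytometry protein
levels, simulated SEM samples) arrive as delimited tables with samples in
rows and nodes in columns.  The K2 score operates on categorical data, so
each column is reduced to a small number of ordinal levels before scoring.
Two codings are offered: ``shared_scale`` (default) bins all columns on one
common amplitude scale, preserving the relative signal magnitudes that
carry causal-direction information in systems with a shared noise scale;
``equal_frequency`` bins each column at its own quantiles, the scale-free
choice for columns in unrelated units.  Three levels is the default
granularity, the common convention for single-cell signalling data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cbn import default_labels

__all__ = [
    "SignalDataset",
    "DiscreteDataset",
    "DiscretizerSpec",
    "load_signal_table",
    "load_signal_tables",
    "write_signal_table",
    "discretize",
]


@dataclass
class SignalDataset:
    """Continuous m x v sample matrix with node labels.

    Parameters
    ----------
    values
        Real matrix, one row per sample, one column per biological node.
    node_labels
        Unique, order-stable column labels.
    source_id
        Free-form provenance tag (file name, simulation id, ...).
    """

    values: np.ndarray
    node_labels: list[str]
    source_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (samples x nodes)")
        m, v = self.values.shape
        if m < 1 or v < 2:
            raise ValueError(f"need at least 1 sample and 2 nodes, got {m}x{v}")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain missing or non-finite entries")
        self.node_labels = [str(x) for x in self.node_labels]
        if len(self.node_labels) != v:
            raise ValueError("node_labels length must match the number of columns")
        if len(set(self.node_labels)) != v:
            raise ValueError("node_labels must be unique")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def v(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.node_labels)


@dataclass
class DiscreteDataset:
    """Integer-level m x v matrix plus per-node cardinalities r_i.

    ``levels[s, i]`` is the level of node i in sample s, in
    ``[0, cardinalities[i])``.  Declared cardinalities may exceed the number
    of observed levels (a node may have possible values never seen in a
    small sample); :func:`discretize` itself only emits realized levels.
    """

    levels: np.ndarray
    cardinalities: list[int]
    node_labels: list[str]

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.ndim != 2:
            raise ValueError("levels must be a 2-D matrix")
        m, v = self.levels.shape
        self.cardinalities = [int(r) for r in self.cardinalities]
        if len(self.cardinalities) != v:
            raise ValueError("cardinalities length must match the number of columns")
        if any(r < 1 for r in self.cardinalities):
            raise ValueError("cardinalities must be positive")
        self.node_labels = [str(x) for x in self.node_labels]
        if len(self.node_labels) != v:
            raise ValueError("node_labels length must match the number of columns")
        if (self.levels < 0).any():
            raise ValueError("levels must be non-negative")
        if (self.levels.max(axis=0) >= np.asarray(self.cardinalities)).any():
            raise ValueError("levels must be below the declared cardinalities")

    @property
    def m(self) -> int:
        return self.levels.shape[0]

    @property
    def v(self) -> int:
        return self.levels.shape[1]


@dataclass
class DiscretizerSpec:
    """How to bin continuous signals.

    ``shared_scale`` (the default) compresses all values with a signed
    log1p transform and cuts equal-width bins on one scale shared by every
    column, so a column's realized levels reflect its amplitude relative
    to the rest of the system — the carrier of causal direction in
    signals whose noise enters on a common scale (see the package's
    methods note).  ``equal_frequency`` cuts each column at its own sample
    quantiles; it is scale-free and appropriate when columns are measured
    in unrelated units, but it also erases all amplitude information.
    """

    method: str = "shared_scale"
    n_bins: int = 3

    def __post_init__(self):
        if self.method not in {"shared_scale", "equal_frequency"}:
            raise ValueError(f"unknown discretization method {self.method!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")


def load_signal_table(
    path: str | Path,
    delimiter: str = "\t",
    has_header: bool | None = None,
) -> SignalDataset:
    """Read a delimited numeric table (samples in rows) into a SignalDataset.

    ``has_header=None`` auto-detects: if any cell of the first row fails to
    parse as a number it is taken as the header.  Generated labels are
    ``X1..Xv`` when no header is present.  A non-numeric data cell raises a
    ValueError naming the offending row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, header=None, dtype=str,
                      skip_blank_lines=True, comment="#",
                      keep_default_na=False)
    if raw.shape[1] < 2:
        raise ValueError(f"{path.name}: need at least 2 columns, got {raw.shape[1]}")

    first = raw.iloc[0]
    first_numeric = pd.to_numeric(first, errors="coerce").notna().all()
    if has_header is None:
        has_header = not first_numeric
    if has_header:
        labels = [str(x).strip() for x in first]
        body = raw.iloc[1:].reset_index(drop=True)
    else:
        labels = default_labels(raw.shape[1])
        body = raw

    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() | body.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        cell = body.iat[r, c]
        raise ValueError(
            f"{path.name}: non-numeric cell {cell!r} at data row {r + 1}, "
            f"column {labels[c]!r}"
        )
    return SignalDataset(numeric.to_numpy(dtype=np.float64), labels, source_id=path.name)


def load_signal_tables(
    source: str | Path | Sequence[str | Path],
    delimiter: str = "\t",
    has_header: bool | None = None,
) -> list[SignalDataset]:
    """Load a directory of tables (sorted by name) or an explicit file list.

    Each table feeds one ant colony; the returned order defines the colony
    index.
    """
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        # a truth edge list written next to simulated tables is not a
        # signal table; skip it in directory mode
        paths = sorted(p for p in Path(source).iterdir()
                       if p.suffix.lower() in {".tsv", ".csv", ".txt"}
                       and p.stem != "truth_edges")
        if not paths:
            raise ValueError(f"no .tsv/.csv/.txt tables found in {source}")
    elif isinstance(source, (str, Path)):
        paths = [Path(source)]
    else:
        paths = [Path(p) for p in source]
    return [load_signal_table(p, delimiter=delimiter, has_header=has_header)
            for p in paths]


def write_signal_table(data: SignalDataset, path: str | Path,
                       delimiter: str = "\t") -> None:
    data.to_frame().to_csv(path, sep=delimiter, index=False)


def _bin_column(col: np.ndarray, edges: np.ndarray | None,
                n_bins: int) -> tuple[np.ndarray, int]:
    distinct = np.unique(col)
    if distinct.size <= n_bins:
        # already (near-)discrete: rank-code the observed values untouched
        return np.searchsorted(distinct, col), int(distinct.size)
    if edges is None:  # per-column equal-frequency boundaries
        edges = np.quantile(col, np.arange(1, n_bins) / n_bins)
    # side="left": a value equal to a boundary falls in the lower bin
    raw = np.searchsorted(edges, col, side="left")
    realized, levels = np.unique(raw, return_inverse=True)
    return levels, int(realized.size)


def _signed_log(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.log1p(np.abs(x))


def discretize(data: SignalDataset, spec: DiscretizerSpec | None = None) -> DiscreteDataset:
    """Reduce every column to a small number of ordinal levels.

    ``shared_scale``: all values are passed through a signed log1p
    transform and cut with equal-width boundaries spanning the pooled
    range of the whole table, so high-amplitude columns realize higher
    levels than low-amplitude ones.  ``equal_frequency``: each column is
    cut at its own ``k/n_bins`` sample quantiles.  In both methods
    boundary ties go to the lower bin, columns with at most ``n_bins``
    distinct values are passed through by rank-coding so exactly discrete
    inputs are not distorted, and cardinalities record realized level
    counts.  A constant column yields a single level with a warning.
    """
    spec = spec or DiscretizerSpec()
    m, v = data.values.shape
    if spec.method == "shared_scale":
        transformed = _signed_log(data.values)
        lo, hi = float(transformed.min()), float(transformed.max())
        shared_edges = lo + (hi - lo) * np.arange(1, spec.n_bins) / spec.n_bins
    else:
        transformed = data.values
        shared_edges = None
    levels = np.empty((m, v), dtype=np.int64)
    cards: list[int] = []
    for i in range(v):
        levels[:, i], r = _bin_column(transformed[:, i], shared_edges, spec.n_bins)
        if r == 1 and np.unique(transformed[:, i]).size > 1:
            # a non-constant column fell entirely inside one shared bin
            # (its amplitude is small relative to the system); split it at
            # its own median so it still carries two levels
            col = transformed[:, i]
            levels[:, i], r = _bin_column(col, np.array([np.median(col)]), 2)
        if r == 1:
            warnings.warn(
                f"column {data.node_labels[i]!r} realizes a single level; "
                "it carries no information for structure learning",
                stacklevel=2,
            )
        cards.append(r)
    return DiscreteDataset(levels, cards, list(data.node_labels))
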