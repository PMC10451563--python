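"""Synthetic linear-SEM benchmark: random DAGs, samples, multi-set bundles.

The generator emulates the standard structure-learning benchmark for
causal discovery: a ground-truth DAG is drawn as a strictly upper
triangular binary matrix with independent Bernoulli(0.5) entries, each
present edge receives a weight uniform on [-1.5, -0.5] U [0.5, 1.5], and
samples solve the linear structural equation model

    x = W^T x + lambda,

where lambda has independent unit-variance noise per node — Gaussian, or a
standardized Gumbel for the non-Gaussian family.  The observed column
order is a random permutation of the generation (topological) order, so
learners cannot exploit variable ordering.  One benchmark bundle shares a
single ground truth and permutation across its N sub-data sets; only the
noise differs, emulating repeated observation of one biological system
(subjects, experimental batches).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import solve_triangular

from .cbn import CBN, default_labels
from .dataset import SignalDataset, write_signal_table
from .metrics import write_edge_list

__all__ = [
    "GroundTruthModel",
    "SimConfig",
    "generate_ground_truth",
    "sample_dataset",
    "generate_benchmark",
    "write_benchmark",
]

_EULER_GAMMA = 0.5772156649015329


@dataclass
class GroundTruthModel:
    """A weighted DAG in generation order plus the observation permutation.

    ``weights`` is strictly upper triangular (hence acyclic); observed
    column j of a sampled data set holds generation variable
    ``permutation[j]``.
    """

    weights: np.ndarray
    adjacency: np.ndarray
    permutation: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if np.tril(w).any():
            raise ValueError("weights must be strictly upper triangular")
        nz = np.abs(w[w != 0])
        if nz.size and (nz.min() < 0.5 or nz.max() > 1.5):
            raise ValueError("nonzero |weights| must lie in [0.5, 1.5]")
        self.adjacency = np.asarray(self.adjacency)
        if not np.array_equal(self.adjacency != 0, w != 0):
            raise ValueError("adjacency must be the nonzero pattern of weights")
        self.permutation = np.asarray(self.permutation, dtype=np.int64)
        if sorted(self.permutation.tolist()) != list(range(w.shape[0])):
            raise ValueError("permutation must be a bijection on node indices")
        self.weights = w

    @property
    def v(self) -> int:
        return self.weights.shape[0]

    def adjacency_observed(self) -> np.ndarray:
        """Truth adjacency conjugated into observed column coordinates."""
        p = self.permutation
        return self.adjacency[np.ix_(p, p)]

    def truth_cbn(self, node_labels=None) -> CBN:
        """Ground truth as a CBN over observed columns."""
        return CBN.from_adjacency(self.adjacency_observed(), node_labels)


@dataclass
class SimConfig:
    """Benchmark bundle parameters (the study conditions, not free dials).

    200 samples per sub-data set, edge probability 0.5 and unit noise
    variance are the benchmark's fixed conditions; v and N vary per
    instance.
    """

    v: int
    N: int
    m: int = 200
    edge_prob: float = 0.5
    noise_family: str = "gaussian"
    noise_variance: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.v < 2 or self.N < 1 or self.m < 1:
            raise ValueError("need v >= 2, N >= 1, m >= 1")
        if not (0.0 <= self.edge_prob <= 1.0):
            raise ValueError("edge_prob must be in [0, 1]")
        if self.noise_family not in {"gaussian", "gumbel"}:
            raise ValueError("noise_family must be 'gaussian' or 'gumbel'")
        if self.noise_variance != 1.0:
            raise ValueError("the benchmark fixes unit noise variance")


def generate_ground_truth(v: int, edge_prob: float = 0.5,
                          rng_seed=0) -> GroundTruthModel:
    """Bernoulli upper-triangular DAG with two-interval uniform weights.

    Each strict-upper entry is present with probability ``edge_prob``;
    present edges get sign from a fair coin and magnitude Unif[0.5, 1.5]
    (together uniform on [-1.5, -0.5] U [0.5, 1.5]).  A uniformly random
    permutation of the node order is drawn and stored.
    """
    if v < 1:
        raise ValueError("v must be >= 1")
    rng = np.random.default_rng(rng_seed)
    upper = np.triu(np.ones((v, v)), k=1)
    present = (rng.random((v, v)) < edge_prob) & (upper > 0)
    signs = np.where(rng.random((v, v)) < 0.5, -1.0, 1.0)
    magnitude = rng.uniform(0.5, 1.5, size=(v, v))
    weights = np.where(present, signs * magnitude, 0.0)
    permutation = rng.permutation(v)
    seed = rng_seed if isinstance(rng_seed, int) else None
    return GroundTruthModel(weights=weights,
                            adjacency=present.astype(np.int8),
                            permutation=permutation, seed=seed)


def _noise(rng: np.random.Generator, shape, family: str) -> np.ndarray:
    if family == "gaussian":
        return rng.standard_normal(shape)
    if family == "gumbel":
        # location/scale chosen for zero mean and unit variance
        scale = math.sqrt(6.0) / math.pi
        loc = -_EULER_GAMMA * scale
        return rng.gumbel(loc=loc, scale=scale, size=shape)
    raise ValueError(f"unknown noise family {family!r}")


def sample_dataset(model: GroundTruthModel, m: int,
                   noise_family: str = "gaussian",
                   rng_seed=0, source_id: str = "") -> SignalDataset:
    """Draw m samples of x = W^T x + lambda, columns in observed order.

    The SEM is solved by forward substitution along the generation
    (topological) order; columns are then reordered by the stored
    permutation and labelled X1..Xv in observed coordinates.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(rng_seed)
    v = model.v
    lam = _noise(rng, (m, v), noise_family)
    # (I - W^T) x = lambda, with I - W^T lower triangular
    a = np.eye(v) - model.weights.T
    x = solve_triangular(a, lam.T, lower=True).T
    observed = x[:, model.permutation]
    return SignalDataset(observed, default_labels(v), source_id=source_id)


def generate_benchmark(cfg: SimConfig) -> tuple[GroundTruthModel, list[SignalDataset]]:
    """One shared ground truth plus N sub-data sets with distinct noise.

    Sub-data set k is sampled with the derived seed (cfg.seed, k); all
    sub-data sets share the truth's permutation.  Evaluate against
    ``model.truth_cbn()`` (observed coordinates).
    """
    model = generate_ground_truth(cfg.v, cfg.edge_prob, rng_seed=[cfg.seed])
    model.seed = cfg.seed
    datasets = [
        sample_dataset(model, cfg.m, cfg.noise_family,
                       rng_seed=[cfg.seed, k], source_id=f"subset{k + 1}")
        for k in range(cfg.N)
    ]
    return model, datasets


def write_benchmark(model: GroundTruthModel, datasets: list[SignalDataset],
                    out_dir: str | Path, cfg: SimConfig | None = None) -> None:
    """Write one TSV per sub-data set, the truth edge list, and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = len(str(len(datasets)))
    for k, d in enumerate(datasets):
        write_signal_table(d, out / f"subset{k + 1:0{width}d}.tsv")
    truth = model.truth_cbn()
    write_edge_list(truth, out / "truth_edges.tsv")
    manifest = {
        "v": model.v,
        "n_subsets": len(datasets),
        "m": datasets[0].m if datasets else None,
        "truth_edges": truth.n_arcs,
        "permutation": model.permutation.tolist(),
        "seed": model.seed,
    }
    if cfg is not None:
        manifest.update({
            "edge_prob": cfg.edge_prob,
            "noise_family": cfg.noise_family,
            "noise_variance": cfg.noise_variance,
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
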