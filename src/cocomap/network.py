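"""Ground-truth network construction.

Builds directed, signed synaptic weight matrices over a population of
excitatory and inhibitory neurons, either with uniform-random (Erdős–Rényi
style) connectivity or with a Watts–Strogatz small-world ring construction,
and selects the randomly observed subset of cells.  Weight conventions:
``weights[i, j]`` is the strength of the connection j -> i, in units of
injected-current increment per presynaptic spike.  A presynaptic cell's sign
is dictated by its type: excitatory columns are non-negative, inhibitory
columns non-positive.  The diagonal is zero (no autapses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WeightSampler",
    "GroundTruthNetwork",
    "assign_cell_types",
    "build_uniform_random_connectivity",
    "build_watts_strogatz_connectivity",
    "select_observed_subset",
    "build_network",
    "save_network",
    "load_network",
]


@dataclass
class WeightSampler:
    """Distribution of synaptic weight magnitudes, per presynaptic type.

    Magnitudes are Uniform(0, max] with separate maxima for excitatory and
    inhibitory presynaptic cells (inhibitory synapses are stronger, keeping
    the classic 2:1 inhibitory/excitatory strength ratio of sparse cortical
    network models).
    """

    exc_max: float = 8.0
    inh_max: float = 16.0

    def magnitudes(self, is_excitatory_pre: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        scale = np.where(is_excitatory_pre, self.exc_max, self.inh_max)
        # 1 - U[0,1) lies in (0, 1]
        return (1.0 - rng.random(is_excitatory_pre.shape)) * scale


@dataclass
class GroundTruthNetwork:
    """The object being mapped: signed weights, cell types, observed subset."""

    weights: np.ndarray  # (n, n), weights[post, pre]
    is_excitatory: np.ndarray  # (n,) bool
    observed: np.ndarray  # sorted indices, len n_obs
    connect_prob: float
    topology: str = "uniform"
    ws_beta: float = field(default=1.0)

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    @property
    def n_obs(self) -> int:
        return len(self.observed)

    def observed_weights(self) -> np.ndarray:
        """Ground-truth weight submatrix over observed cells (post x pre)."""
        return self.weights[np.ix_(self.observed, self.observed)]

    def validate(self) -> None:
        w, exc = self.weights, self.is_excitatory
        if w.shape[0] != w.shape[1] or w.shape[0] != exc.shape[0]:
            raise ValueError("inconsistent network shapes")
        if np.any(np.diag(w) != 0):
            raise ValueError("autapses present on the diagonal")
        if np.any(w[:, exc] < 0) or np.any(w[:, ~exc] > 0):
            raise ValueError("column signs inconsistent with cell types")


def assign_cell_types(
    total_cells: int, excitatory_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Randomly place excitatory/inhibitory labels over the population.

    Exactly round(excitatory_fraction * total_cells) cells are excitatory
    (round-half-up), at positions randomised by ``rng``.  Returns a boolean
    array, True = excitatory.
    """
    if total_cells <= 0:
        raise ValueError("total_cells must be positive")
    if not 0.0 <= excitatory_fraction <= 1.0:
        raise ValueError("excitatory_fraction must lie in [0, 1]")
    n_exc = int(np.floor(excitatory_fraction * total_cells + 0.5))
    labels = np.zeros(total_cells, dtype=bool)
    labels[:n_exc] = True
    return labels[rng.permutation(total_cells)]


def _signed_weights(
    mask: np.ndarray,
    is_excitatory: np.ndarray,
    weight_sampler: WeightSampler,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fill a boolean adjacency mask with signed magnitudes by presynaptic type."""
    n = mask.shape[0]
    mags = weight_sampler.magnitudes(np.broadcast_to(is_excitatory, (n, n)), rng)
    signs = np.where(is_excitatory, 1.0, -1.0)  # broadcast over columns
    return np.where(mask, mags * signs, 0.0)


def build_uniform_random_connectivity(
    is_excitatory: np.ndarray,
    connect_prob: float,
    rng: np.random.Generator,
    weight_sampler: WeightSampler | None = None,
) -> GroundTruthNetwork:
    """Each ordered off-diagonal pair is connected independently with
    probability ``connect_prob``; connected weights are drawn from
    ``weight_sampler`` with the sign forced by the presynaptic label."""
    if not 0.0 <= connect_prob <= 1.0:
        raise ValueError("connect_prob must lie in [0, 1]")
    weight_sampler = weight_sampler or WeightSampler()
    n = len(is_excitatory)
    mask = rng.random((n, n)) < connect_prob
    np.fill_diagonal(mask, False)
    weights = _signed_weights(mask, is_excitatory, weight_sampler, rng)
    return GroundTruthNetwork(
        weights=weights,
        is_excitatory=np.asarray(is_excitatory, dtype=bool),
        observed=np.arange(n),
        connect_prob=connect_prob,
        topology="uniform",
    )


def ws_out_degree(connect_prob: float, n: int) -> int:
    """Ring-lattice out-degree: nearest even integer to connect_prob*(n-1)."""
    return 2 * int(np.floor(connect_prob * (n - 1) / 2.0 + 0.5))


def build_watts_strogatz_connectivity(
    is_excitatory: np.ndarray,
    connect_prob: float,
    ws_beta: float,
    rng: np.random.Generator,
    weight_sampler: WeightSampler | None = None,
) -> GroundTruthNetwork:
    """Directed Watts–Strogatz small-world network.

    Starts from a directed ring lattice in which each node projects to its
    k/2 nearest neighbours on each side, with k the nearest even integer to
    ``connect_prob * (n - 1)``.  Each edge's *target* endpoint is then
    independently rewired with probability ``ws_beta`` to a uniformly chosen
    node, rejecting self-loops and duplicate edges by resampling.  Rewiring
    conserves the total edge count, so expected density matches the
    uniform-random construction.  Signed weights are assigned to the final
    edges by presynaptic cell type.
    """
    if not 0.0 <= ws_beta <= 1.0:
        raise ValueError("ws_beta must lie in [0, 1]")
    weight_sampler = weight_sampler or WeightSampler()
    n = len(is_excitatory)
    k = ws_out_degree(connect_prob, n)
    if k < 2:
        raise ValueError(
            f"connect_prob={connect_prob} gives ring out-degree k={k} < 2; "
            f"minimum density for a {n}-node ring lattice is about {1.0 / (n - 1):.4g}"
        )
    targets: list[set[int]] = []
    for j in range(n):
        targets.append({(j + m) % n for m in range(1, k // 2 + 1)}
                       | {(j - m) % n for m in range(1, k // 2 + 1)})
    for j in range(n):
        for t in sorted(targets[j]):
            if rng.random() < ws_beta:
                targets[j].discard(t)
                while True:
                    new = int(rng.integers(n))
                    if new != j and new not in targets[j]:
                        targets[j].add(new)
                        break
    mask = np.zeros((n, n), dtype=bool)
    for j in range(n):
        mask[np.fromiter(targets[j], dtype=int), j] = True
    weights = _signed_weights(mask, is_excitatory, weight_sampler, rng)
    return GroundTruthNetwork(
        weights=weights,
        is_excitatory=np.asarray(is_excitatory, dtype=bool),
        observed=np.arange(n),
        connect_prob=connect_prob,
        topology="watts_strogatz",
        ws_beta=ws_beta,
    )


def select_observed_subset(
    total_cells: int, n_obs: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample without replacement of the cells we get to record."""
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    if n_obs > total_cells:
        raise ValueError("n_obs cannot exceed total_cells")
    return np.sort(rng.choice(total_cells, size=n_obs, replace=False))


def build_network(config, rng: np.random.Generator) -> GroundTruthNetwork:
    """Build the ground-truth network described by an ExperimentConfig."""
    labels = assign_cell_types(config.total_cells, config.excitatory_fraction, rng)
    sampler = WeightSampler(exc_max=config.w_exc_max, inh_max=config.w_inh_max)
    if config.topology == "watts_strogatz":
        net = build_watts_strogatz_connectivity(
            labels, config.sparsity, config.ws_beta, rng, sampler
        )
    else:
        net = build_uniform_random_connectivity(labels, config.sparsity, rng, sampler)
    net.observed = select_observed_subset(config.total_cells, config.n_obs, rng)
    return net


# -- import/export --------------------------------------------------------


def save_network(net: GroundTruthNetwork, directory: str | Path) -> None:
    """Write weights (dense CSV + edge list), labels and observed set."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ids = np.arange(net.n_cells)
    pd.DataFrame(net.weights, columns=ids).to_csv(d / "weights.csv", index=False)
    post, pre = np.nonzero(net.weights)
    pd.DataFrame(
        {"pre": pre, "post": post, "weight": net.weights[post, pre]}
    ).to_csv(d / "edges.csv", index=False)
    pd.DataFrame(
        {"id": ids, "type": np.where(net.is_excitatory, "excitatory", "inhibitory")}
    ).to_csv(d / "labels.csv", index=False)
    np.savetxt(d / "observed.txt", net.observed, fmt="%d")


def load_network(directory: str | Path) -> GroundTruthNetwork:
    d = Path(directory)
    weights = pd.read_csv(d / "weights.csv").to_numpy(dtype=float)
    labels = pd.read_csv(d / "labels.csv")["type"].to_numpy() == "excitatory"
    observed = np.loadtxt(d / "observed.txt", dtype=int, ndmin=1)
    n = weights.shape[0]
    density = float((weights != 0).sum() / (n * (n - 1))) if n > 1 else 0.0
    net = GroundTruthNetwork(
        weights=weights, is_excitatory=labels, observed=observed, connect_prob=density
    )
    net.validate()
    return net
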