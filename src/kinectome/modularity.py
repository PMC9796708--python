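"""Community structure of kinectomes: Louvain, consensus, allegiance.

Communities are found by modularity maximization,

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / (2m)] * delta(c_i, c_j),

with m the total edge weight, k_i the weighted degree of node i, and delta
the Kronecker delta on community labels.  Louvain is a greedy, seeded
optimizer of Q; a single run is a local optimum, so partitions are
stabilized by consensus clustering: many seeded runs are summarized in a
co-assignment matrix, sub-chance entries are zeroed, and the matrix is
re-clustered until co-assignment becomes binary.  Modularity assumes
non-negative weights, so correlation matrices are mapped through the
absolute value (default) or by zeroing negative edges before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import Kinectome

__all__ = [
    "Partition",
    "AllegianceMatrix",
    "to_adjacency",
    "modularity_q",
    "louvain",
    "consensus_cluster",
    "allegiance",
    "group_communities",
]


@dataclass
class Partition:
    """Community labels per node, contiguous from 0, with their Q value."""

    community_id: np.ndarray
    q_value: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.community_id, dtype=int)
        self.community_id = _canonicalize(labels)
        if not -1 - 1e-12 <= self.q_value <= 1 + 1e-12:
            raise ValueError("Q must lie in [-1, 1]")

    @property
    def n_communities(self) -> int:
        return int(self.community_id.max()) + 1


@dataclass
class AllegianceMatrix:
    """Probability of pairwise co-assignment across partitions."""

    matrix: np.ndarray
    n_partitions: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if np.abs(m - m.T).max() > 1e-12:
            raise ValueError("allegiance matrix must be symmetric")
        if m.min() < 0 or m.max() > 1 + 1e-12:
            raise ValueError("allegiance entries must lie in [0, 1]")
        self.matrix = m


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 0..K-1 in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        out[i] = mapping.setdefault(int(lab), len(mapping))
    return out


def to_adjacency(k: Kinectome, negatives: str = "abs") -> np.ndarray:
    """Kinectome -> non-negative adjacency (zero diagonal).

    ``negatives="abs"`` keeps coupling strength regardless of sign;
    ``"zero"`` discards anti-correlated edges.
    """
    m = k.matrix.copy()
    np.fill_diagonal(m, 0.0)
    if negatives == "abs":
        return np.abs(m)
    if negatives == "zero":
        return np.clip(m, 0.0, None)
    raise ValueError("negatives must be 'abs' or 'zero'")


def _check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(a - a.T).max() > 1e-9:
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0:
        raise ValueError("adjacency weights must be non-negative")
    if a.sum() == 0:
        raise ValueError("adjacency has no edges (m = 0)")
    return a


def modularity_q(adjacency: np.ndarray, partition: Partition | np.ndarray) -> float:
    """Newman modularity Q of a partition on a weighted graph."""
    a = _check_adjacency(adjacency)
    labels = (
        partition.community_id
        if isinstance(partition, Partition)
        else np.asarray(partition, dtype=int)
    )
    if len(labels) != a.shape[0]:
        raise ValueError("partition length does not match adjacency size")
    two_m = a.sum()
    k = a.sum(axis=1)
    delta = labels[:, None] == labels[None, :]
    return float(((a - np.outer(k, k) / two_m) * delta).sum() / two_m)


def louvain(
    adjacency: np.ndarray, seed: int, resolution: float = 1.0
) -> Partition:
    """Seeded Louvain community detection on a weighted graph."""
    a = _check_adjacency(adjacency)
    g = nx.from_numpy_array(a)
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=int(seed)
    )
    labels = np.empty(a.shape[0], dtype=int)
    for cid, members in enumerate(communities):
        for node in members:
            labels[node] = cid
    return Partition(community_id=labels, q_value=modularity_q(a, labels))


def _coassignment(partitions: list[np.ndarray]) -> np.ndarray:
    stack = np.stack(partitions)  # runs x nodes
    agree = stack[:, :, None] == stack[:, None, :]
    return agree.mean(axis=0)


def _chance_coassignment(partitions: list[np.ndarray],
                         rng: np.random.Generator) -> float:
    """Expected co-assignment under node-permuted (null) partitions."""
    total = 0.0
    for labels in partitions:
        perm = rng.permutation(labels)
        d = _coassignment([perm])
        n = len(labels)
        iu = np.triu_indices(n, k=1)
        total += d[iu].mean()
    return total / len(partitions)


def consensus_cluster(
    adjacency: np.ndarray,
    n_iter: int = 100,
    seed: int = 0,
    resolution: float = 1.0,
    max_rounds: int = 50,
) -> Partition:
    """Consensus clustering over repeated seeded Louvain runs.

    Louvain is run ``n_iter`` times with distinct sub-seeds; the
    co-assignment matrix is thresholded at the chance level estimated from
    label-permuted partitions and re-clustered until it is binary.  The
    returned Q is evaluated on the *original* adjacency.
    """
    original = _check_adjacency(adjacency)
    rng = np.random.default_rng(seed)
    current = original
    for _ in range(max_rounds):
        sub_seeds = rng.integers(0, 2**31 - 1, size=n_iter)
        parts = [
            louvain(current, seed=int(s), resolution=resolution).community_id
            for s in sub_seeds
        ]
        d = _coassignment(parts)
        if np.all((d == 0) | (d == 1)):
            labels = parts[0]
            return Partition(
                community_id=labels, q_value=modularity_q(original, labels)
            )
        threshold = _chance_coassignment(parts, rng)
        d = np.where(d < threshold, 0.0, d)
        np.fill_diagonal(d, 0.0)
        if d.sum() == 0:  # everything sub-chance: no structure to refine
            labels = parts[0]
            return Partition(
                community_id=labels, q_value=modularity_q(original, labels)
            )
        current = d
    raise RuntimeError(
        f"consensus clustering did not converge in {max_rounds} rounds"
    )


def allegiance(partitions: list[Partition]) -> AllegianceMatrix:
    """Fraction of partitions assigning each marker pair together."""
    if not partitions:
        raise ValueError("need at least one partition")
    sizes = {len(p.community_id) for p in partitions}
    if len(sizes) != 1:
        raise ValueError("partitions cover different marker counts")
    d = _coassignment([p.community_id for p in partitions])
    return AllegianceMatrix(matrix=d, n_partitions=len(partitions))


def group_communities(
    alleg: AllegianceMatrix,
    seed: int = 0,
    n_iter: int = 100,
) -> Partition:
    """Group-level modules: consensus clustering of an allegiance matrix."""
    a = alleg.matrix.copy()
    np.fill_diagonal(a, 0.0)
    return consensus_cluster(a, n_iter=n_iter, seed=seed)
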