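"""Construction and group-level comparison of kinectomes.

A kinectome is the marker x marker matrix of Pearson correlations between
the per-marker acceleration (or jerk) time series along one movement axis:
the whole-body movement network of one trial.  With 21 markers it has 420
off-diagonal entries of which 210 are unique; those 210 upper-triangle
edges feed every downstream analysis.  Correlation (normalized covariance)
rather than raw covariance is used so that edge weights are bounded and
scale-free, which the fingerprinting and degree analyses presuppose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AXES, MarkerTrial
from .kinematics import QUANTITIES, AxisSeriesMatrix, axis_series
from .stats import PermutationResult, permutation_compare, permutation_test_groups

__all__ = [
    "Kinectome",
    "EdgeVector",
    "build_kinectome",
    "trial_kinectomes",
    "vectorize",
    "unvectorize",
    "edge_index_pairs",
    "group_edge_stats",
    "compare_group_means",
    "compare_group_variability",
]

_SYMMETRY_TOL = 1e-9


@dataclass
class Kinectome:
    """Symmetric correlation matrix of one (quantity, axis) pair."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    subject_id: str = ""
    session: str = ""
    quantity: str = ""
    axis: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if np.abs(m - m.T).max() > _SYMMETRY_TOL:
            raise ValueError("kinectome matrix must be symmetric")
        if np.abs(np.diag(m) - 1.0).max() > _SYMMETRY_TOL:
            raise ValueError("kinectome diagonal must be 1")
        if m.min() < -1 - _SYMMETRY_TOL or m.max() > 1 + _SYMMETRY_TOL:
            raise ValueError("correlations must lie in [-1, 1]")
        self.matrix = m

    @property
    def n_markers(self) -> int:
        return len(self.labels)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.labels,
                     columns=self.labels).to_csv(path, float_format="%.17g")
        sidecar = Path(path).with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {"subject_id": self.subject_id, "session": self.session,
                 "quantity": self.quantity, "axis": self.axis},
                fh, indent=1, sort_keys=True)


@dataclass
class EdgeVector:
    """Unique upper-triangle edges of a kinectome, in row-major order."""

    values: np.ndarray
    edge_index: tuple[tuple[str, str], ...]
    subject_id: str = ""
    session: str = ""
    quantity: str = ""
    axis: str = ""


def edge_index_pairs(labels: tuple[str, ...]) -> tuple[tuple[str, str], ...]:
    """Row-major upper-triangle (marker_i, marker_j) pairs, i < j."""
    n = len(labels)
    return tuple(
        (labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)
    )


def build_kinectome(series: AxisSeriesMatrix, subject_id: str | None = None,
                    session: str | None = None) -> Kinectome:
    """Pearson-correlate every pair of marker series into a kinectome."""
    values = np.asarray(series.values, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 frames to correlate")
    sd = values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [series.labels[i] for i in dead]
        raise ValueError(f"zero-variance series for markers {names}")
    matrix = np.corrcoef(values.T)
    matrix = np.clip((matrix + matrix.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(matrix, 1.0)
    return Kinectome(
        matrix=matrix,
        labels=tuple(series.labels),
        subject_id=subject_id if subject_id is not None else series.subject_id,
        session=session if session is not None else series.session,
        quantity=series.quantity,
        axis=series.axis,
    )


def trial_kinectomes(
    trial: MarkerTrial,
    quantities: tuple[str, ...] = QUANTITIES,
    axes: tuple[str, ...] = AXES,
    filter_cutoff_hz: float | None = None,
) -> dict[tuple[str, str], Kinectome]:
    """All (quantity, axis) kinectomes of one trial (6 by default)."""
    return {
        (q, a): build_kinectome(
            axis_series(trial, q, a, filter_cutoff_hz=filter_cutoff_hz)
        )
        for q in quantities
        for a in axes
    }


def vectorize(k: Kinectome) -> EdgeVector:
    """Extract the unique upper-triangle edges (diagonal excluded)."""
    if np.abs(k.matrix - k.matrix.T).max() > _SYMMETRY_TOL:
        raise ValueError("matrix asymmetry exceeds tolerance")
    iu = np.triu_indices(k.n_markers, k=1)
    return EdgeVector(
        values=k.matrix[iu].copy(),
        edge_index=edge_index_pairs(k.labels),
        subject_id=k.subject_id,
        session=k.session,
        quantity=k.quantity,
        axis=k.axis,
    )


def unvectorize(edges: EdgeVector, labels: tuple[str, ...]) -> np.ndarray:
    """Reassemble the symmetric matrix (unit diagonal) from an edge vector."""
    n = len(labels)
    if len(edges.values) != n * (n - 1) // 2:
        raise ValueError("edge vector length does not match label count")
    m = np.eye(n)
    iu = np.triu_indices(n, k=1)
    m[iu] = edges.values
    m[(iu[1], iu[0])] = edges.values
    return m


def _check_same_kind(kinectomes: list[Kinectome]) -> None:
    first = kinectomes[0]
    for k in kinectomes[1:]:
        if (k.labels, k.quantity, k.axis) != (
            first.labels, first.quantity, first.axis
        ):
            raise ValueError(
                "kinectomes mix labels/quantities/axes and cannot be pooled"
            )


def group_edge_stats(kinectomes: list[Kinectome], stat: str = "mean") -> np.ndarray:
    """Element-wise across-subject mean or sample SD of kinectome matrices."""
    if len(kinectomes) < 2:
        raise ValueError("need at least 2 kinectomes")
    _check_same_kind(kinectomes)
    stack = np.stack([k.matrix for k in kinectomes])
    if stat == "mean":
        return stack.mean(axis=0)
    if stat == "sd":
        return stack.std(axis=0, ddof=1)
    raise ValueError(f"stat must be 'mean' or 'sd', got {stat!r}")


def _mean_over_edges(matrices: np.ndarray) -> float:
    n = matrices.shape[-1]
    iu = np.triu_indices(n, k=1)
    return float(matrices[..., iu[0], iu[1]].mean())


def compare_group_means(
    group_a: list[Kinectome],
    group_b: list[Kinectome],
    n_perm: int = 10000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test on the per-subject mean edge weight."""
    _check_same_kind(group_a + group_b)
    iu = np.triu_indices(group_a[0].n_markers, k=1)
    a = [float(k.matrix[iu].mean()) for k in group_a]
    b = [float(k.matrix[iu].mean()) for k in group_b]
    return permutation_compare(a, b, n_perm=n_perm, seed=seed)


def compare_group_variability(
    group_a: list[Kinectome],
    group_b: list[Kinectome],
    n_perm: int = 10000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test on within-group kinectome variability.

    The statistic is the absolute difference of the two groups'
    mean-over-edges of the element-wise SD matrix; subject labels are
    shuffled and the group SD matrices recomputed at each permutation.
    """
    _check_same_kind(group_a + group_b)
    stack = np.stack([k.matrix for k in group_a + group_b])
    n = stack.shape[-1]
    iu = np.triu_indices(n, k=1)
    edges = stack[:, iu[0], iu[1]]  # subjects x 210

    def sd_gap(a: np.ndarray, b: np.ndarray) -> float:
        return abs(
            float(a.std(axis=0, ddof=1).mean())
            - float(b.std(axis=0, ddof=1).mean())
        )

    # permutation_test_groups shuffles rows; wrap the edge rows as "values"
    idx = np.arange(len(edges))

    def stat(ia: np.ndarray, ib: np.ndarray) -> float:
        return sd_gap(edges[ia.astype(int)], edges[ib.astype(int)])

    return permutation_test_groups(
        idx.astype(float), len(group_a), stat, n_perm=n_perm, seed=seed
    )
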