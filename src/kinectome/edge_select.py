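"""Edge reliability ranking and edge-count identification-rate curves.

Per-edge test-retest stability is measured by the one-way random-effects
intraclass correlation, ICC = (MSA - MSW) / (MSA + (k-1) MSW), with
subjects as clusters and the k = 2 sessions as observations.  Edges are
ranked by descending ICC and the identification rate (IR) is recomputed on
growing edge subsets (3, 4, ..., all), yielding an IR curve; its validity
is checked against null curves built from random edge subsets.  The edges
needed to first exceed a target IR (99% by default) are the "edges of
interest"; markers on which those edges preferentially hinge, beyond what
equally sized random subsets produce, are flagged as significant nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fingerprint import _cross_corr
from .network import EdgeVector

__all__ = [
    "ICCResult",
    "IRCurve",
    "edge_icc",
    "icc_edge_order",
    "ir_curve",
    "null_ir_curves",
    "edges_of_interest",
    "node_occurrence_significance",
]


@dataclass
class ICCResult:
    per_edge_icc: np.ndarray  # NaN where undefined (zero total variance)
    msa_per_edge: np.ndarray
    msw_per_edge: np.ndarray
    k: int = 2


@dataclass
class IRCurve:
    edge_counts: np.ndarray
    ir_values: np.ndarray
    edge_order: np.ndarray
    null_mean: np.ndarray | None = None
    null_p95: np.ndarray | None = None
    null_p99: np.ndarray | None = None


def _stacked(test: Sequence[EdgeVector], retest: Sequence[EdgeVector]):
    t = np.stack([v.values for v in test])
    r = np.stack([v.values for v in retest])
    if t.shape != r.shape or t.shape[0] < 2:
        raise ValueError("need aligned test/retest sets of >= 2 subjects")
    return t, r


def edge_icc(
    test: Sequence[EdgeVector], retest: Sequence[EdgeVector]
) -> ICCResult:
    """One-way ICC of every edge across the two sessions."""
    t, r = _stacked(test, retest)
    n = t.shape[0]
    k = 2
    subj_mean = (t + r) / 2.0
    grand = subj_mean.mean(axis=0)
    msa = k * ((subj_mean - grand) ** 2).sum(axis=0) / (n - 1)
    msw = (((t - subj_mean) ** 2) + ((r - subj_mean) ** 2)).sum(axis=0) / (
        n * (k - 1)
    )
    denom = msa + (k - 1) * msw
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, (msa - msw) / denom, np.nan)
    return ICCResult(per_edge_icc=icc, msa_per_edge=msa, msw_per_edge=msw, k=k)


def _ir_from_stacks(t: np.ndarray, r: np.ndarray) -> float:
    """Identification rate from stacked (N, E) test/retest matrices."""
    m = _cross_corr(t, r)
    diag = np.diag(m).copy()
    off = m.copy()
    np.fill_diagonal(off, -np.inf)
    others_max = np.maximum(off.max(axis=1), off.max(axis=0))
    return float(np.mean(diag > others_max))


def icc_edge_order(icc: ICCResult) -> np.ndarray:
    """Edge indices in descending ICC order.

    Undefined (NaN) ICCs rank last; ties (and NaNs) break stably by edge
    index so the ordering is reproducible.
    """
    values = icc.per_edge_icc
    keys = np.where(np.isnan(values), -np.inf, values)
    return np.argsort(-keys, kind="stable")


def ir_curve(
    test: Sequence[EdgeVector],
    retest: Sequence[EdgeVector],
    edge_order: np.ndarray,
    start: int = 3,
) -> IRCurve:
    """IR as a function of the number of top-ranked edges included."""
    n_edges = len(test[0].values)
    order = np.asarray(edge_order, dtype=int)
    if sorted(order.tolist()) != list(range(n_edges)):
        raise ValueError("edge_order must be a permutation of all edge indices")
    t, r = _stacked(test, retest)
    counts = np.arange(start, n_edges + 1)
    irs = np.empty(len(counts))
    for i, c in enumerate(counts):
        irs[i] = _ir_from_stacks(t[:, order[:c]], r[:, order[:c]])
    return IRCurve(edge_counts=counts, ir_values=irs, edge_order=order)


def null_ir_curves(
    test: Sequence[EdgeVector],
    retest: Sequence[EdgeVector],
    n_null: int = 100,
    seed: int | None = None,
    start: int = 3,
) -> dict[str, np.ndarray]:
    """Null IR band from randomly selected edge subsets.

    For each edge count c, ``n_null`` IRs are computed on uniformly random
    c-edge subsets (without replacement); the per-count mean and 95th/99th
    percentiles are returned.
    """
    rng = np.random.default_rng(seed)
    t, r = _stacked(test, retest)
    n_edges = len(test[0].values)
    counts = np.arange(start, n_edges + 1)
    irs = np.empty((len(counts), n_null))
    for i, c in enumerate(counts):
        for j in range(n_null):
            subset = rng.choice(n_edges, size=c, replace=False)
            irs[i, j] = _ir_from_stacks(t[:, subset], r[:, subset])
    return {
        "edge_counts": counts,
        "mean": irs.mean(axis=1),
        "p95": np.percentile(irs, 95, axis=1),
        "p99": np.percentile(irs, 99, axis=1),
    }


def edges_of_interest(
    curve: IRCurve, ir_threshold: float = 0.99
) -> np.ndarray:
    """First edges (in ranking order) at which IR exceeds the threshold.

    Returns an empty array if the curve never exceeds the threshold.
    """
    above = np.flatnonzero(curve.ir_values > ir_threshold)
    if above.size == 0:
        warnings.warn(
            f"IR curve never exceeds {ir_threshold}; no edges of interest",
            stacklevel=2,
        )
        return np.empty(0, dtype=int)
    c_star = int(curve.edge_counts[above[0]])
    return curve.edge_order[:c_star].copy()


def node_occurrence_significance(
    edge_sets: Sequence[np.ndarray],
    edge_index: Sequence[tuple[str, str]],
    labels: Sequence[str],
    n_null: int = 10000,
    ci: float = 0.99,
    seed: int | None = None,
) -> dict:
    """Markers on which pooled edges of interest hinge above chance.

    ``edge_sets`` holds one edge-index array per analysis parameter (e.g.
    ML/AP x acceleration/jerk); occurrences are endpoint counts over the
    pooled sets.  The null resamples equally sized uniform edge subsets and
    flags markers whose observed count exceeds the upper bound of the
    1-99% style interval, i.e. the ``ci`` (99th) percentile of the
    per-marker null counts.
    """
    if not edge_sets or all(len(s) == 0 for s in edge_sets):
        raise ValueError("edge sets are empty")
    labels = list(labels)
    n_markers = len(labels)
    endpoint_idx = np.array(
        [[labels.index(a), labels.index(b)] for a, b in edge_index]
    )
    rng = np.random.default_rng(seed)

    def count_endpoints(sets: Sequence[np.ndarray]) -> np.ndarray:
        counts = np.zeros(n_markers, dtype=int)
        for s in sets:
            if len(s):
                np.add.at(counts, endpoint_idx[np.asarray(s, int)].ravel(), 1)
        return counts

    observed = count_endpoints(edge_sets)
    n_edges = len(edge_index)
    sizes = [len(s) for s in edge_sets if len(s)]
    null_counts = np.empty((n_null, n_markers), dtype=int)
    for i in range(n_null):
        draws = [rng.choice(n_edges, size=sz, replace=False) for sz in sizes]
        null_counts[i] = count_endpoints(draws)
    upper = np.percentile(null_counts, 100 * ci, axis=0)
    lower = np.percentile(null_counts, 100 * (1 - ci), axis=0)
    flagged = [labels[i] for i in range(n_markers) if observed[i] > upper[i]]
    return {
        "flagged": flagged,
        "occurrences": dict(zip(labels, observed.tolist())),
        "upper_bound": dict(zip(labels, upper.tolist())),
        "lower_bound": dict(zip(labels, lower.tolist())),
    }
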