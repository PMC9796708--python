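"""Test-retest identifiability of movement networks.

Each subject contributes two edge vectors, one per gait recording ("test"
and "retest").  The identifiability matrix (IM) holds the Pearson
correlation between every test vector (rows) and every retest vector
(columns); it is square but not symmetric.  From it:

- I-self: mean of the diagonal (self-similarity across sessions);
- I-others: mean of the off-diagonal (between-subject similarity);
- I-diff = I-self - I-others (differential identifiability);
- IR (identification rate): the fraction of subjects whose self-similarity
  exceeds every one of their cross-subject similarities.

A subject's cross-subject similarities are taken over both the row and the
column of the IM (both match directions must lose to self); ties count as
not identified.  Scores are plain correlations in [0, 1]-ish units; the
reporting layer multiplies by 100 where percentages are wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import EdgeVector
from .stats import PermutationResult, permutation_compare

__all__ = [
    "IdentifiabilityMatrix",
    "FingerprintScores",
    "identifiability_matrix",
    "fingerprint_scores",
    "compare_fingerprints",
]


@dataclass
class IdentifiabilityMatrix:
    matrix: np.ndarray  # rows = test, columns = retest
    subject_order: tuple[str, ...]
    quantity: str = ""
    axis: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.subject_order)
        if m.shape != (n, n):
            raise ValueError("matrix must be square over the subject order")
        if np.abs(m).max() > 1 + 1e-9:
            raise ValueError("IM entries must lie in [-1, 1]")
        self.matrix = m


@dataclass
class FingerprintScores:
    iself_per_subject: np.ndarray
    iothers_per_subject: np.ndarray
    iself: float
    iothers: float
    idiff: float
    ir: float


def _cross_corr(test: np.ndarray, retest: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation between two (N, E) matrices."""
    t = test - test.mean(axis=1, keepdims=True)
    r = retest - retest.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(t, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(tn == 0) or np.any(rn == 0):
        raise ValueError("zero-variance edge vector; cannot correlate")
    return np.clip((t / tn[:, None]) @ (r / rn[:, None]).T, -1.0, 1.0)


def identifiability_matrix(
    test: Sequence[EdgeVector],
    retest: Sequence[EdgeVector],
    edge_subset: Sequence[int] | None = None,
) -> IdentifiabilityMatrix:
    """Correlate test edge vectors (rows) with retest vectors (columns).

    ``edge_subset`` restricts the correlation to the given edge indices.
    Test and retest sequences must be aligned subject-by-subject and share
    an edge index.
    """
    if len(test) != len(retest) or len(test) < 2:
        raise ValueError("need equal test/retest lists of at least 2 subjects")
    edge_index = test[0].edge_index
    for v in list(test) + list(retest):
        if v.edge_index != edge_index:
            raise ValueError("edge vectors have inconsistent edge indices")
    order = tuple(v.subject_id for v in test)
    if tuple(v.subject_id for v in retest) != order:
        raise ValueError("test and retest subject orders differ")
    t = np.stack([v.values for v in test])
    r = np.stack([v.values for v in retest])
    if edge_subset is not None:
        idx = np.asarray(edge_subset, dtype=int)
        if idx.size == 0 or idx.min() < 0 or idx.max() >= t.shape[1]:
            raise ValueError("invalid edge subset indices")
        t = t[:, idx]
        r = r[:, idx]
    return IdentifiabilityMatrix(
        matrix=_cross_corr(t, r),
        subject_order=order,
        quantity=test[0].quantity,
        axis=test[0].axis,
    )


def fingerprint_scores(im: IdentifiabilityMatrix) -> FingerprintScores:
    """Summarize an identifiability matrix into I-self/I-others/I-diff/IR."""
    m = im.matrix
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    diag = np.diag(m).copy()
    off_mask = ~np.eye(n, dtype=bool)
    iothers_global = float(m[off_mask].mean())
    iothers_per = np.empty(n)
    identified = np.zeros(n, dtype=bool)
    for i in range(n):
        others = np.concatenate([m[i, :i], m[i, i + 1:],
                                 m[:i, i], m[i + 1:, i]])
        iothers_per[i] = others.mean()
        identified[i] = diag[i] > others.max()  # ties are not identified
    iself = float(diag.mean())
    return FingerprintScores(
        iself_per_subject=diag,
        iothers_per_subject=iothers_per,
        iself=iself,
        iothers=iothers_global,
        idiff=iself - iothers_global,
        ir=float(identified.mean()),
    )


def compare_fingerprints(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    n_perm: int = 10000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation comparison of per-subject fingerprint scores.

    The family of such comparisons in a full study is 18 (3 scores x 6
    kinectome types), giving a Bonferroni cutoff of 0.05/18.
    """
    return permutation_compare(scores_a, scores_b, n_perm=n_perm, seed=seed)
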