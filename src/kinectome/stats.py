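"""Permutation testing and rank correlation utilities.

Group differences throughout the package are assessed non-parametrically:
the observed statistic is the absolute difference of group means, and its
null distribution is built by shuffling the pooled group labels.  P-values
use the add-one Monte-Carlo correction, p = (#{null >= observed} + 1) /
(n_perm + 1), so they always lie in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "permutation_compare",
    "permutation_test_groups",
    "spearman_corr",
    "bonferroni_cutoff",
]


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None

    def significant(self, alpha: float = 0.05, n_tests: int = 1) -> bool:
        return self.p_value < bonferroni_cutoff(alpha, n_tests)


def bonferroni_cutoff(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Family-wise significance cutoff alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def permutation_test_groups(
    values: np.ndarray,
    n_a: int,
    stat: Callable[[np.ndarray, np.ndarray], float],
    n_perm: int = 10000,
    seed: int | None = None,
) -> PermutationResult:
    """Generic two-group label-shuffling permutation test.

    ``values`` holds group A's per-subject values followed by group B's
    (``n_a`` in group A); ``stat`` maps (a_values, b_values) to a scalar.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    if not 0 < n_a < len(values):
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    observed = float(stat(values[:n_a], values[n_a:]))
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(values)
        null[i] = stat(perm[:n_a], perm[n_a:])
    p = (np.count_nonzero(null >= observed) + 1) / (n_perm + 1)
    return PermutationResult(
        observed_stat=observed,
        null_stats=null,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
    )


def _abs_mean_diff(a: np.ndarray, b: np.ndarray) -> float:
    return abs(float(np.mean(a)) - float(np.mean(b)))


def permutation_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 10000,
    seed: int | None = None,
) -> PermutationResult:
    """Absolute-mean-difference permutation test between two groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    return permutation_test_groups(
        np.concatenate([a, b]), len(a), _abs_mean_diff, n_perm=n_perm,
        seed=seed,
    )


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need two equal-length samples of at least 4 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
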