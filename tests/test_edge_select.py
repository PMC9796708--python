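"""ICC edge ranking, IR curves, null bands, and node occurrence."""

import numpy as np
import pytest

import kinectome as kc
from kinectome.edge_select import (
    edge_icc,
    edges_of_interest,
    icc_edge_order,
    ir_curve,
    node_occurrence_significance,
    null_ir_curves,
)
from kinectome.fingerprint import fingerprint_scores, identifiability_matrix
from kinectome.network import EdgeVector, edge_index_pairs


def vectors(values, session="test"):
    values = np.asarray(values, dtype=float)
    n_edges = values.shape[1]
    labels = tuple(f"M{i}" for i in range(n_edges + 1))
    pairs = edge_index_pairs(labels)[:n_edges]
    return [
        EdgeVector(values=row, edge_index=pairs, subject_id=f"S{i}",
                   session=session)
        for i, row in enumerate(values)
    ]


def anova_icc_oracle(test, retest):
    """Independent one-way ANOVA decomposition, explicit loops per edge."""
    n, n_edges = test.shape
    k = 2
    out = np.empty(n_edges)
    for e in range(n_edges):
        data = np.stack([test[:, e], retest[:, e]], axis=1)  # n x k
        subj_means = data.mean(axis=1)
        grand = data.mean()
        ss_among = k * sum((m - grand) ** 2 for m in subj_means)
        ss_within = sum(
            (data[i, j] - subj_means[i]) ** 2
            for i in range(n) for j in range(k)
        )
        msa = ss_among / (n - 1)
        msw = ss_within / (n * (k - 1))
        out[e] = (msa - msw) / (msa + (k - 1) * msw)
    return out


class TestEdgeICC:
    def test_perfect_retest_gives_unit_icc(self, rng):
        t = rng.normal(size=(10, 15))
        icc = edge_icc(vectors(t), vectors(t, "retest"))
        np.testing.assert_allclose(icc.per_edge_icc, 1.0)
        np.testing.assert_allclose(icc.msw_per_edge, 0.0, atol=1e-15)

    def test_crossed_two_subject_case(self):
        # test/retest = (0,1) and (1,0): MSA = 0, MSW = 0.5, ICC = -1
        t = np.array([[0.0], [1.0]])
        r = np.array([[1.0], [0.0]])
        icc = edge_icc(vectors(t), vectors(r, "retest"))
        assert icc.msa_per_edge[0] == pytest.approx(0.0)
        assert icc.msw_per_edge[0] == pytest.approx(0.5)
        assert icc.per_edge_icc[0] == pytest.approx(-1.0)

    def test_matches_anova_oracle(self, rng):
        t = rng.normal(size=(20, 30))
        r = t + rng.normal(size=(20, 30), scale=0.5)
        icc = edge_icc(vectors(t), vectors(r, "retest"))
        np.testing.assert_allclose(
            icc.per_edge_icc, anova_icc_oracle(t, r), atol=1e-9
        )

    def test_invariant_to_common_constant(self, rng):
        t = rng.normal(size=(12, 8))
        r = t + rng.normal(size=(12, 8), scale=0.3)
        base = edge_icc(vectors(t), vectors(r, "retest")).per_edge_icc
        shifted = edge_icc(
            vectors(t + 7.5), vectors(r + 7.5, "retest")
        ).per_edge_icc
        np.testing.assert_allclose(shifted, base, atol=1e-9)

    def test_zero_variance_edge_recorded_missing_and_ranked_last(self, rng):
        t = rng.normal(size=(8, 5))
        r = t + rng.normal(size=(8, 5), scale=0.2)
        t[:, 2] = 1.0
        r[:, 2] = 1.0  # no variance at all for edge 2
        icc = edge_icc(vectors(t), vectors(r, "retest"))
        assert np.isnan(icc.per_edge_icc[2])
        order = icc_edge_order(icc)
        assert order[-1] == 2

    def test_stable_tie_break_by_edge_index(self):
        t = np.array([[0.0, 0.0, 1.0], [1.0, 1.0, 0.0], [2.0, 2.0, 0.5]])
        r = t.copy()  # edges 0 and 1 have identical (unit) ICC
        icc = edge_icc(vectors(t), vectors(r, "retest"))
        order = icc_edge_order(icc)
        assert list(order[:2]) == [0, 1]


class TestIRCurve:
    def test_full_count_equals_plain_fingerprint_ir(self, rng):
        t = rng.normal(size=(8, 50))
        r = t + rng.normal(size=(8, 50), scale=0.4)
        test, retest = vectors(t), vectors(r, "retest")
        order = icc_edge_order(edge_icc(test, retest))
        curve = ir_curve(test, retest, order)
        full_ir = fingerprint_scores(
            identifiability_matrix(test, retest)
        ).ir
        assert curve.edge_counts[0] == 3
        assert curve.edge_counts[-1] == 50
        assert curve.ir_values[-1] == pytest.approx(full_ir)

    def test_noiseless_cohort_perfect_everywhere(self, rng):
        t = rng.normal(size=(6, 20))
        test, retest = vectors(t), vectors(t, "retest")
        order = np.arange(20)
        curve = ir_curve(test, retest, order)
        np.testing.assert_allclose(curve.ir_values, 1.0)

    def test_invalid_edge_order_rejected(self, rng):
        t = rng.normal(size=(5, 10))
        with pytest.raises(ValueError, match="permutation"):
            ir_curve(vectors(t), vectors(t, "retest"), np.zeros(10, dtype=int))

    def test_null_band_deterministic_under_seed(self, rng):
        t = rng.normal(size=(5, 12))
        r = t + rng.normal(size=(5, 12), scale=0.5)
        test, retest = vectors(t), vectors(r, "retest")
        b1 = null_ir_curves(test, retest, n_null=10, seed=3)
        b2 = null_ir_curves(test, retest, n_null=10, seed=3)
        np.testing.assert_array_equal(b1["mean"], b2["mean"])
        np.testing.assert_array_equal(b1["p99"], b2["p99"])


class TestPlantedSignature:
    def test_icc_ordering_recovers_signature_edges(self):
        test, retest, signature = kc.planted_edge_cohort(seed=5)
        icc = edge_icc(test, retest)
        order = icc_edge_order(icc)
        assert set(order[:20]) == set(signature)

    def test_curve_reaches_unit_ir_quickly_and_dominates_null(self):
        test, retest, _ = kc.planted_edge_cohort(seed=5)
        order = icc_edge_order(edge_icc(test, retest))
        curve = ir_curve(test, retest, order)
        null = null_ir_curves(test, retest, n_null=30, seed=0)
        first_unit = curve.edge_counts[np.argmax(curve.ir_values >= 1.0)]
        assert first_unit <= 25
        assert np.all(curve.ir_values >= null["mean"] - 1e-12)


class TestEdgesOfInterest:
    def _toy_curve(self, ir_values, start=3):
        n = len(ir_values) + start - 1
        return kc.IRCurve(
            edge_counts=np.arange(start, n + 1),
            ir_values=np.asarray(ir_values, dtype=float),
            edge_order=np.arange(n),
        )

    def test_first_count_exceeding_threshold(self):
        curve = self._toy_curve([0.5, 0.8, 0.95, 1.0, 1.0])
        edges = edges_of_interest(curve, ir_threshold=0.99)
        assert len(edges) == 6  # counts start at 3; 1.0 first at count 6
        np.testing.assert_array_equal(edges, np.arange(6))

    def test_threshold_zero_returns_minimum_count(self):
        curve = self._toy_curve([0.5, 0.8, 0.9])
        assert len(edges_of_interest(curve, ir_threshold=0.0)) == 3

    def test_never_exceeded_warns_and_returns_empty(self):
        curve = self._toy_curve([0.1, 0.2, 0.3])
        with pytest.warns(UserWarning, match="never exceeds"):
            assert len(edges_of_interest(curve, ir_threshold=0.99)) == 0

    def test_matches_linear_scan_oracle(self, rng):
        values = np.sort(rng.uniform(0, 1, size=30))
        curve = self._toy_curve(values)
        threshold = 0.7
        edges = edges_of_interest(curve, ir_threshold=threshold)
        scan = next(
            (c for c, v in zip(curve.edge_counts, values) if v > threshold),
            None,
        )
        assert len(edges) == (scan or 0)


class TestNodeOccurrence:
    def test_star_concentration_flagged(self):
        labels = [f"M{i}" for i in range(21)]
        pairs = edge_index_pairs(tuple(labels))
        star = np.array([i for i, p in enumerate(pairs) if "M0" in p][:15])
        result = node_occurrence_significance(
            [star], pairs, labels, n_null=500, seed=0
        )
        assert "M0" in result["flagged"]

    def test_uniform_sets_rarely_flag(self, rng):
        labels = [f"M{i}" for i in range(21)]
        pairs = edge_index_pairs(tuple(labels))
        flags = 0
        for i in range(20):
            edges = rng.choice(210, size=25, replace=False)
            result = node_occurrence_significance(
                [edges], pairs, labels, n_null=300, seed=i
            )
            flags += len(result["flagged"])
        # 21 markers x 20 draws at the 1% level: expect ~4 flags, allow slack
        assert flags <= 15

    def test_deterministic_under_seed(self, rng):
        labels = [f"M{i}" for i in range(21)]
        pairs = edge_index_pairs(tuple(labels))
        edges = rng.choice(210, size=30, replace=False)
        r1 = node_occurrence_significance([edges], pairs, labels,
                                          n_null=200, seed=9)
        r2 = node_occurrence_significance([edges], pairs, labels,
                                          n_null=200, seed=9)
        assert r1["flagged"] == r2["flagged"]
        assert r1["upper_bound"] == r2["upper_bound"]

    def test_empty_sets_rejected(self):
        labels = [f"M{i}" for i in range(21)]
        pairs = edge_index_pairs(tuple(labels))
        with pytest.raises(ValueError, match="empty"):
            node_occurrence_significance([np.array([], dtype=int)],
                                         pairs, labels)
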