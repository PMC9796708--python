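"""Marker sets, trial reading/writing, and session validation."""

import numpy as np
import pandas as pd
import pytest

import kinectome as kc
from kinectome import c3d
from kinectome.markers import MarkerSet


def small_set():
    return MarkerSet(
        labels=("T10", "R_ANK", "L_ANK"),
        anatomical_group={"T10": "trunk", "R_ANK": "leg", "L_ANK": "leg"},
    )


def write_delimited(path, positions, labels):
    data = {"frame": np.arange(positions.shape[0])}
    for i, lab in enumerate(labels):
        for j, suf in enumerate(("_x", "_y", "_z")):
            data[lab + suf] = positions[:, i, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


class TestMarkerSet:
    def test_default_set_invariants(self):
        ms = kc.default_marker_set()
        assert len(ms) == 21
        assert ms.n_edges == 210
        assert "T10" in ms.labels
        assert len(set(ms.labels)) == 21
        lefts = [m for m in ms.labels if ms.side[m] == "left"]
        rights = [m for m in ms.labels if ms.side[m] == "right"]
        assert len(lefts) == len(rights) == 8
        assert len(ms.homologous_pairs()) == 8

    @pytest.mark.parametrize(
        "labels",
        [
            ("T10", "T10", "L_ANK"),  # duplicate
            ("C7", "R_ANK", "L_ANK"),  # trunk anchor missing
            ("T10", "R_ANK", "L_HEE"),  # unmatched side pair
        ],
    )
    def test_invalid_sets_rejected(self, labels):
        with pytest.raises(ValueError):
            MarkerSet(labels=labels, anatomical_group={})

    def test_marker_map_file_round_trip(self, tmp_path):
        import json

        doc = {"labels": list(kc.DEFAULT_MARKER_LABELS)}
        path = tmp_path / "markers.json"
        path.write_text(json.dumps(doc))
        ms = MarkerSet.from_file(path)
        assert ms.labels == kc.DEFAULT_MARKER_LABELS


class TestDelimited:
    def test_shape_bookkeeping(self, tmp_path, rng):
        pos = rng.normal(size=(10, 3, 3))
        path = tmp_path / "trial.csv"
        write_delimited(path, pos, small_set().labels)
        trial = kc.read_trial(path, "S1", "test", marker_set=small_set())
        assert trial.positions.shape == (10, 3, 3)

    def test_axis_map_permutation(self, tmp_path, rng):
        pos = rng.normal(size=(10, 3, 3))
        path = tmp_path / "trial.csv"
        write_delimited(path, pos, small_set().labels)
        swapped = kc.read_trial(
            path, "S1", "test", marker_set=small_set(),
            axis_map={"ML": 1, "AP": 0, "V": 2},
        )
        # ML series of the output is the file's column-1 (y) series
        np.testing.assert_array_equal(
            swapped.axis_positions("ML"), pos[:, :, 1]
        )
        np.testing.assert_array_equal(
            swapped.axis_positions("AP"), pos[:, :, 0]
        )

    def test_axis_remap_involution(self, tmp_path, rng):
        pos = rng.normal(size=(8, 3, 3))
        path = tmp_path / "trial.csv"
        write_delimited(path, pos, small_set().labels)
        fwd = {"ML": 2, "AP": 0, "V": 1}
        trial = kc.read_trial(path, "S1", "test", marker_set=small_set(),
                              axis_map=fwd)
        # applying the inverse map to the permuted data restores the input
        inv = np.empty(3, dtype=int)
        for k, (axis, col) in enumerate(fwd.items()):
            inv[col] = list(fwd).index(axis)
        np.testing.assert_array_equal(trial.positions[:, :, inv], pos)

    def test_round_trip_full_precision(self, tmp_path, rng):
        pos = rng.normal(size=(12, 21, 3))
        trial = kc.MarkerTrial("S1", "test", pos, 120.0)
        path = tmp_path / "out.csv"
        kc.write_trial_delimited(trial, path)
        back = kc.read_trial(path, "S1", "test")
        np.testing.assert_array_equal(back.positions, pos)
        assert back.sampling_rate == pytest.approx(120.0)

    def test_missing_marker_column_names_label(self, tmp_path, rng):
        pos = rng.normal(size=(10, 2, 3))
        path = tmp_path / "trial.csv"
        write_delimited(path, pos, ["T10", "R_ANK"])
        with pytest.raises(ValueError, match="L_ANK"):
            kc.read_trial(path, "S1", "test", marker_set=small_set())

    def test_gap_fill_policy(self, tmp_path):
        t = np.arange(30.0)
        pos = np.stack([np.stack([t, t**2, np.sin(t)], axis=1)] * 3, axis=1)
        pos[10:13, 0, 1] = np.nan  # 3-frame gap in a smooth column
        path = tmp_path / "trial.csv"
        write_delimited(path, pos, small_set().labels)
        with pytest.raises(ValueError, match="missing"):
            kc.read_trial(path, "S1", "test", marker_set=small_set())
        trial = kc.read_trial(path, "S1", "test", marker_set=small_set(),
                              fill_max_gap=5)
        filled = trial.positions[10:13, 0, 1]
        np.testing.assert_allclose(filled, t[10:13] ** 2, rtol=1e-6)
        with pytest.raises(ValueError, match="gap longer"):
            kc.read_trial(path, "S1", "test", marker_set=small_set(),
                          fill_max_gap=2)

    def test_millimeter_conversion(self, tmp_path, rng):
        pos = rng.normal(size=(10, 3, 3)) * 1000
        path = tmp_path / "trial.csv"
        write_delimited(path, pos, small_set().labels)
        trial = kc.read_trial(path, "S1", "test", marker_set=small_set(),
                              units="mm")
        np.testing.assert_allclose(trial.positions, pos / 1000.0)


class TestC3D:
    def test_write_read_round_trip_bit_equal(self, tmp_path, rng):
        pos = rng.normal(size=(25, 4, 3)).astype(np.float32)
        labels = ["T10", "C7", "R_ANK", "L_ANK"]
        path = tmp_path / "trial.c3d"
        c3d.write_c3d(path, pos, labels, rate=120.0)
        content = c3d.read_c3d(path)
        assert content.labels == labels
        assert content.rate == pytest.approx(120.0)
        np.testing.assert_array_equal(content.positions, pos)

    def test_read_trial_c3d_orders_markers(self, tmp_path, rng):
        pos = rng.normal(size=(10, 3, 3)).astype(np.float32)
        path = tmp_path / "trial.c3d"
        # file stores markers in a different order than the marker set
        c3d.write_c3d(path, pos, ["L_ANK", "T10", "R_ANK"], rate=100.0)
        trial = kc.read_trial(path, "S1", "test", format="c3d",
                              marker_set=small_set())
        np.testing.assert_array_equal(trial.positions[:, 0], pos[:, 1])
        np.testing.assert_array_equal(trial.positions[:, 1], pos[:, 2])
        assert trial.sampling_rate == pytest.approx(100.0)

    def test_millimeter_units_declared_in_file(self, tmp_path, rng):
        pos = (rng.normal(size=(10, 3, 3)) * 100).astype(np.float32)
        path = tmp_path / "trial.c3d"
        c3d.write_c3d(path, pos, list(small_set().labels), rate=120.0,
                      units="mm")
        trial = kc.read_trial(path, "S1", "test", format="c3d",
                              marker_set=small_set())
        np.testing.assert_allclose(
            trial.positions, pos.astype(float) / 1000.0
        )

    def test_missing_label_in_c3d(self, tmp_path, rng):
        pos = rng.normal(size=(10, 2, 3)).astype(np.float32)
        path = tmp_path / "trial.c3d"
        c3d.write_c3d(path, pos, ["T10", "R_ANK"], rate=120.0)
        with pytest.raises(ValueError, match="L_ANK"):
            kc.read_trial(path, "S1", "test", format="c3d",
                          marker_set=small_set())


class TestValidateSession:
    def _trial(self, sid, session, rng, rate=120.0):
        return kc.MarkerTrial(sid, session, rng.normal(size=(10, 21, 3)),
                              rate)

    def _subjects(self, sids):
        return pd.DataFrame({
            "subject_id": sids,
            "group": "HC",
            "age": 60,
            "sex": "F",
            "education": 12,
            "motor_score": 0.0,
        })

    def test_pairs_all_subjects(self, rng):
        sids = [f"S{i:02d}" for i in range(23)]
        trials = [
            self._trial(s, sess, rng) for s in sids
            for sess in ("test", "retest")
        ]
        pairs = kc.validate_session(trials, self._subjects(sids))
        assert len(pairs) == 23
        assert all(p[0].session == "test" for p in pairs.values())

    def test_single_trial_subject_named_in_error(self, rng):
        trials = [self._trial("S1", "test", rng)]
        with pytest.raises(ValueError, match="S1"):
            kc.validate_session(trials, self._subjects(["S1"]))

    def test_mismatched_sampling_rates(self, rng):
        trials = [self._trial("S1", "test", rng, 120.0),
                  self._trial("S1", "retest", rng, 100.0)]
        with pytest.raises(ValueError, match="sampling rates"):
            kc.validate_session(trials, self._subjects(["S1"]))

    def test_unknown_subject(self, rng):
        trials = [self._trial("S9", "test", rng),
                  self._trial("S9", "retest", rng)]
        with pytest.raises(ValueError, match="unknown subject"):
            kc.validate_session(trials, self._subjects(["S1"]))

    def test_subject_table_validation(self):
        bad = self._subjects(["S1"]).drop(columns=["motor_score"])
        with pytest.raises(ValueError, match="motor_score"):
            kc.io.validate_subjects(bad)
        neg = self._subjects(["S1"]).assign(motor_score=-1.0)
        with pytest.raises(ValueError, match="non-negative"):
            kc.io.validate_subjects(neg)
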