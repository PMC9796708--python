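"""Reading, writing, and validating marker-trajectory trials.

A trial is one short gait recording (a complete gait cycle or two, ~2 s at
120 frames/s) of every marker in a :class:`~kinectome.markers.MarkerSet`.
Two trials per subject ("test" and "retest") are required by the
fingerprinting analyses.  Supported on-disk formats are delimited text
(header ``frame,<label>_x,<label>_y,<label>_z,...``) and binary C3D.
Positions are held internally in meters with axis columns ordered
(mediolateral, anteroposterior, vertical).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from . import c3d
from .markers import MarkerSet, default_marker_set

__all__ = [
    "AXES",
    "MarkerTrial",
    "read_trial",
    "write_trial_delimited",
    "load_subjects",
    "validate_session",
]

AXES: tuple[str, str, str] = ("ML", "AP", "V")
IDENTITY_AXIS_MAP: dict[str, int] = {"ML": 0, "AP": 1, "V": 2}

GROUP_LABELS = ("HS", "HC", "PD")
SUBJECT_COLUMNS = ("subject_id", "group", "age", "sex", "education",
                   "motor_score")


@dataclass
class MarkerTrial:
    """One gait-cycle recording of a full marker set.

    ``positions`` has shape (frames, markers, 3) in meters with axis columns
    already in internal (ML, AP, V) order; ``marker_set.labels`` gives the
    marker order along the second dimension.
    """

    subject_id: str
    session: str  # "test" or "retest"
    positions: np.ndarray
    sampling_rate: float = 120.0
    marker_set: MarkerSet = field(default_factory=default_marker_set)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.session not in ("test", "retest"):
            raise ValueError(f"session must be test/retest, got {self.session!r}")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, markers, 3)")
        if self.positions.shape[0] < 5:
            raise ValueError("a trial needs at least 5 frames")
        if self.positions.shape[1] != len(self.marker_set):
            raise ValueError(
                f"marker count {self.positions.shape[1]} does not match the "
                f"{len(self.marker_set)}-marker set"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain missing/non-finite values")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def axis_positions(self, axis: str) -> np.ndarray:
        """frames x markers positions along one axis ("ML", "AP", "V")."""
        return self.positions[:, :, AXES.index(axis)]


def _check_axis_map(axis_map: dict[str, int] | None) -> dict[str, int]:
    if axis_map is None:
        return dict(IDENTITY_AXIS_MAP)
    if set(axis_map) != set(AXES) or sorted(axis_map.values()) != [0, 1, 2]:
        raise ValueError(
            "axis_map must assign ML/AP/V to the three file columns exactly "
            f"once, got {axis_map!r}"
        )
    return dict(axis_map)


def _apply_axis_map(raw: np.ndarray, axis_map: dict[str, int]) -> np.ndarray:
    order = [axis_map[a] for a in AXES]
    return raw[:, :, order]


def _fill_gaps(col: np.ndarray, max_gap: int, name: str) -> np.ndarray:
    """Cubic-spline fill of NaN runs no longer than max_gap frames."""
    bad = ~np.isfinite(col)
    if not bad.any():
        return col
    if max_gap <= 0:
        raise ValueError(
            f"column {name!r} has missing frames and gap filling is disabled"
        )
    idx = np.flatnonzero(bad)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    if any(len(r) > max_gap for r in runs):
        raise ValueError(
            f"column {name!r} has a gap longer than {max_gap} frames"
        )
    if bad[0] or bad[-1]:
        raise ValueError(f"column {name!r} is missing its first/last frame")
    good = np.flatnonzero(~bad)
    spline = CubicSpline(good, col[good])
    out = col.copy()
    out[bad] = spline(np.flatnonzero(bad))
    return out


def read_trial(
    path: str | Path,
    subject_id: str,
    session: str,
    format: str = "delimited",
    marker_set: MarkerSet | None = None,
    axis_map: dict[str, int] | None = None,
    units: str = "m",
    fill_max_gap: int = 0,
) -> MarkerTrial:
    """Read one trial from disk.

    Parameters
    ----------
    format
        ``"delimited"`` (CSV with ``frame,<label>_x,...`` header) or
        ``"c3d"``.
    axis_map
        Which file column (0/1/2 within each marker triplet) carries each of
        ML, AP, V.  Defaults to the identity mapping x=ML, y=AP, z=V.
    units
        Units of the delimited file ("m" or "mm"); C3D files declare their
        own units.
    fill_max_gap
        If > 0, NaN gaps of at most this many consecutive frames are filled
        by cubic interpolation; longer gaps (or any gap when 0) are an error.
    """
    marker_set = marker_set or default_marker_set()
    axis_map = _check_axis_map(axis_map)
    path = Path(path)
    if format == "delimited":
        # round_trip parsing keeps 17-significant-digit files bit-exact
        table = pd.read_csv(path, float_precision="round_trip")
        cols = []
        for label in marker_set.labels:
            for suffix in ("_x", "_y", "_z"):
                col = label + suffix
                if col not in table.columns:
                    raise ValueError(
                        f"{path}: missing column {col!r} for marker {label!r}"
                    )
                cols.append(col)
        raw = table[cols].to_numpy(dtype=float)
        raw = np.stack(
            [
                np.column_stack(
                    [_fill_gaps(raw[:, 3 * i + j], fill_max_gap,
                                cols[3 * i + j]) for j in range(3)]
                )
                for i in range(len(marker_set))
            ],
            axis=1,
        )
        file_units = units
        rate = 120.0
        if "time_s" in table.columns and len(table) > 1:
            rate = 1.0 / float(np.mean(np.diff(table["time_s"])))
    elif format == "c3d":
        content = c3d.read_c3d(path)
        missing = [
            lab for lab in marker_set.labels if lab not in content.labels
        ]
        if missing:
            raise ValueError(f"{path}: missing marker labels {missing}")
        order = [content.labels.index(lab) for lab in marker_set.labels]
        raw = np.asarray(content.positions, dtype=float)[:, order, :]
        for i, lab in enumerate(marker_set.labels):
            for j in range(3):
                raw[:, i, j] = _fill_gaps(raw[:, i, j], fill_max_gap,
                                          f"{lab}[{j}]")
        file_units = content.units
        rate = content.rate
    else:
        raise ValueError(f"unknown trial format {format!r}")

    if file_units == "mm":
        raw = raw / 1000.0
    elif file_units != "m":
        raise ValueError(f"unsupported units {file_units!r}")
    return MarkerTrial(
        subject_id=subject_id,
        session=session,
        positions=_apply_axis_map(raw, axis_map),
        sampling_rate=rate,
        marker_set=marker_set,
    )


def write_trial_delimited(trial: MarkerTrial, path: str | Path) -> None:
    """Write a trial as delimited text (full float precision)."""
    n = trial.n_frames
    data: dict[str, np.ndarray] = {"frame": np.arange(n)}
    data["time_s"] = np.arange(n) / trial.sampling_rate
    for i, label in enumerate(trial.marker_set.labels):
        for j, suffix in enumerate(("_x", "_y", "_z")):
            data[label + suffix] = trial.positions[:, i, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def load_subjects(path: str | Path) -> pd.DataFrame:
    """Load and validate the subject metadata table (CSV)."""
    table = pd.read_csv(path)
    return validate_subjects(table)


def validate_subjects(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(SUBJECT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"subject table missing columns {sorted(missing)}")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"]
        raise ValueError(f"duplicate subject ids: {sorted(set(dup))}")
    bad = set(table["group"]) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if (table["motor_score"] < 0).any():
        raise ValueError("motor_score must be non-negative")
    return table.reset_index(drop=True)


def validate_session(
    trials: list[MarkerTrial], subjects: pd.DataFrame
) -> dict[str, tuple[MarkerTrial, MarkerTrial]]:
    """Pair each subject's test/retest trials, enforcing session invariants.

    Returns ``{subject_id: (test_trial, retest_trial)}``.  Raises if any
    subject has anything other than exactly one test and one retest trial
    with identical marker sets and sampling rates, or if a trial references
    a subject absent from the metadata table.
    """
    known = set(subjects["subject_id"].astype(str))
    by_subject: dict[str, list[MarkerTrial]] = {}
    for trial in trials:
        if trial.subject_id not in known:
            raise ValueError(
                f"trial references unknown subject {trial.subject_id!r}"
            )
        by_subject.setdefault(trial.subject_id, []).append(trial)

    bad_counts = sorted(
        sid for sid, ts in by_subject.items() if len(ts) != 2
    )
    if bad_counts:
        raise ValueError(
            f"subjects without exactly 2 trials: {bad_counts}"
        )
    pairs: dict[str, tuple[MarkerTrial, MarkerTrial]] = {}
    for sid, ts in by_subject.items():
        sessions = sorted(t.session for t in ts)
        if sessions != ["retest", "test"]:
            raise ValueError(
                f"subject {sid!r} needs one test and one retest trial, "
                f"got {sessions}"
            )
        test = next(t for t in ts if t.session == "test")
        retest = next(t for t in ts if t.session == "retest")
        if test.marker_set.labels != retest.marker_set.labels:
            raise ValueError(f"subject {sid!r}: trial marker sets differ")
        if test.sampling_rate != retest.sampling_rate:
            raise ValueError(f"subject {sid!r}: trial sampling rates differ")
        pairs[sid] = (test, retest)
    return pairs
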