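"""Canonical marker sets for whole-body gait acquisitions.

The default set covers the whole body with 21 markers in the style of the
Davis protocol used in clinical gait analysis: head (front/back), trunk
(C7, T10), shoulders, elbows, wrists, pelvis (sacrum and both anterior
superior iliac spines), knees, ankles, heels, and toes.  The 10th thoracic
vertebra marker ("T10") anchors the trunk and must always be present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["MarkerSet", "DEFAULT_MARKER_LABELS", "default_marker_set"]

DEFAULT_MARKER_LABELS: tuple[str, ...] = (
    "HEAD_F", "HEAD_B", "C7", "T10",
    "R_SHO", "L_SHO", "R_ELB", "L_ELB", "R_WRI", "L_WRI",
    "SACR", "R_ASIS", "L_ASIS",
    "R_KNE", "L_KNE", "R_ANK", "L_ANK",
    "R_HEE", "L_HEE", "R_TOE", "L_TOE",
)

_DEFAULT_GROUPS: dict[str, str] = {
    "HEAD_F": "head", "HEAD_B": "head",
    "C7": "trunk", "T10": "trunk",
    "R_SHO": "upper_arm", "L_SHO": "upper_arm",
    "R_ELB": "upper_arm", "L_ELB": "upper_arm",
    "R_WRI": "forearm", "L_WRI": "forearm",
    "SACR": "pelvis", "R_ASIS": "pelvis", "L_ASIS": "pelvis",
    "R_KNE": "leg", "L_KNE": "leg", "R_ANK": "leg", "L_ANK": "leg",
    "R_HEE": "foot", "L_HEE": "foot", "R_TOE": "foot", "L_TOE": "foot",
}

VALID_GROUPS = frozenset(
    {"head", "trunk", "upper_arm", "forearm", "pelvis", "leg", "foot"}
)


def _infer_side(label: str) -> str:
    if label.startswith("R_"):
        return "right"
    if label.startswith("L_"):
        return "left"
    return "midline"


@dataclass(frozen=True)
class MarkerSet:
    """Ordered set of body markers with side and anatomical-group labels.

    Invariants (enforced at construction): labels unique, left/right markers
    come in matched pairs, the trunk anchor marker (default ``T10``) exists,
    and every anatomical group label is one of the seven canonical groups.
    """

    labels: tuple[str, ...]
    side: dict[str, str] = field(default_factory=dict)
    anatomical_group: dict[str, str] = field(default_factory=dict)
    trunk_anchor: str = "T10"

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            raise ValueError("marker labels must be unique")
        if not self.side:
            object.__setattr__(
                self, "side", {lab: _infer_side(lab) for lab in labels}
            )
        if not self.anatomical_group and set(labels) <= set(_DEFAULT_GROUPS):
            object.__setattr__(
                self,
                "anatomical_group",
                {lab: _DEFAULT_GROUPS[lab] for lab in labels},
            )
        missing = set(labels) - set(self.side)
        if missing:
            raise ValueError(f"side missing for markers: {sorted(missing)}")
        bad = {g for g in self.anatomical_group.values()} - VALID_GROUPS
        if bad:
            raise ValueError(f"unknown anatomical groups: {sorted(bad)}")
        if self.trunk_anchor not in labels:
            raise ValueError(
                f"trunk anchor marker {self.trunk_anchor!r} not in marker set"
            )
        lefts = {lab[2:] for lab in labels if self.side[lab] == "left"}
        rights = {lab[2:] for lab in labels if self.side[lab] == "right"}
        if lefts != rights:
            raise ValueError(
                "left/right markers must come in matched pairs; "
                f"unmatched: {sorted(lefts ^ rights)}"
            )

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def n_edges(self) -> int:
        """Number of unique (upper-triangle) marker pairs."""
        n = len(self.labels)
        return n * (n - 1) // 2

    def homologous_pairs(self) -> list[tuple[str, str]]:
        """(left, right) label pairs of bilaterally homologous markers."""
        return [
            ("L_" + lab[2:], lab)
            for lab in self.labels
            if self.side[lab] == "right"
        ]

    def markers_in_groups(self, groups: set[str] | frozenset[str]) -> list[str]:
        return [
            lab for lab in self.labels if self.anatomical_group[lab] in groups
        ]

    @classmethod
    def from_file(cls, path: str | Path) -> "MarkerSet":
        """Load a marker map from JSON.

        Expected keys: ``labels`` (list, required), ``side`` and
        ``anatomical_group`` (dicts, optional), ``trunk_anchor`` (optional).
        """
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            labels=tuple(doc["labels"]),
            side=doc.get("side", {}),
            anatomical_group=doc.get("anatomical_group", {}),
            trunk_anchor=doc.get("trunk_anchor", "T10"),
        )


def default_marker_set() -> MarkerSet:
    """The 21-marker whole-body set used throughout the package."""
    return MarkerSet(labels=DEFAULT_MARKER_LABELS)
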