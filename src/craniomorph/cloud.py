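"""Core marker-cloud data model.

A head cloud is a fixed set of 138 marker slots: 135 coded cap markers
plus three reference stickers (front, left preauricular, right
preauricular).  Every marker contributes four ordered 3-D vertices in
millimetres.  Cap markers may be absent (undetected); the three
reference stickers are mandatory because they define the coordinate
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from craniomorph.errors import CloudSchemaError

#: Number of marker slots (135 cap markers + 3 reference stickers).
N_SLOTS = 138
#: Number of coded cap markers.
N_CAP_MARKERS = 135
#: Slot ids (1-based) of the three reference stickers.
SLOT_REF_FRONT = 136
SLOT_REF_LEFT = 137
SLOT_REF_RIGHT = 138
REF_SLOTS = (SLOT_REF_FRONT, SLOT_REF_LEFT, SLOT_REF_RIGHT)

#: Minimum number of present markers for a usable cloud.
MIN_PRESENT = 131
#: Maximum number of droppable cap markers.
MAX_MISSING = N_SLOTS - MIN_PRESENT  # 7

#: The six cranial-shape classes.
CLASSES = (
    "brachycephaly",
    "dolichocephaly",
    "normocephaly",
    "plagiocephaly",
    "towering",
    "trigonocephaly",
)

#: Fixed numeric label encoding.
LABEL_CODES = {
    "brachycephaly": 1,
    "dolichocephaly": 2,
    "towering": 3,
    "trigonocephaly": 4,
    "plagiocephaly": 5,
    "normocephaly": 6,
}
CODE_TO_CLASS = {v: k for k, v in LABEL_CODES.items()}

ROLES = ("cap", "ref_front", "ref_left", "ref_right")


def slot_role(slot: int) -> str:
    """Role of a 1-based marker slot."""
    if 1 <= slot <= N_CAP_MARKERS:
        return "cap"
    if slot == SLOT_REF_FRONT:
        return "ref_front"
    if slot == SLOT_REF_LEFT:
        return "ref_left"
    if slot == SLOT_REF_RIGHT:
        return "ref_right"
    raise CloudSchemaError(f"marker slot {slot} outside 1..{N_SLOTS}")


@dataclass
class HeadCloud:
    """One marker-labelled 3-D head point cloud.

    Parameters
    ----------
    cloud_id : str
        Unique identifier of this cloud.
    base_id : str
        Identifier of the original cloud an augmented copy derives
        from (equals ``cloud_id`` for originals).
    class_label : str
        One of :data:`CLASSES`.
    vertices : ndarray of shape (138, 4, 3)
        Vertex coordinates in mm, indexed by 0-based slot. Absent
        slots hold NaN.
    present : ndarray of shape (138,), bool
        Presence flag per slot.
    provenance : str or mapping
        ``"original"`` or an augmentation record.
    meta : dict
        Free-form generator metadata (e.g. effective shape parameters).
    """

    cloud_id: str
    base_id: str
    class_label: str
    vertices: np.ndarray
    present: np.ndarray
    provenance: Any = "original"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        self.validate()

    # -- schema -------------------------------------------------------

    def validate(self) -> None:
        """Enforce the marker-schema invariants; raise CloudSchemaError."""
        if self.class_label not in CLASSES:
            raise CloudSchemaError(f"unknown class label {self.class_label!r}")
        if self.vertices.shape != (N_SLOTS, 4, 3):
            raise CloudSchemaError(
                f"vertices must have shape ({N_SLOTS}, 4, 3), got {self.vertices.shape}"
            )
        if self.present.shape != (N_SLOTS,):
            raise CloudSchemaError(f"present mask must have shape ({N_SLOTS},)")
        for slot in REF_SLOTS:
            if not self.present[slot - 1]:
                raise CloudSchemaError(
                    f"reference sticker slot {slot} must always be present"
                )
        n = int(self.present.sum())
        if not (MIN_PRESENT <= n <= N_SLOTS):
            raise CloudSchemaError(
                f"present marker count {n} outside [{MIN_PRESENT}, {N_SLOTS}]"
            )
        if not np.isfinite(self.vertices[self.present]).all():
            raise CloudSchemaError("present markers must have finite coordinates")

    # -- derived quantities -------------------------------------------

    @property
    def n_present(self) -> int:
        return int(self.present.sum())

    @property
    def n_vertices(self) -> int:
        return 4 * self.n_present

    @property
    def label_code(self) -> int:
        return LABEL_CODES[self.class_label]

    def marker_vertices(self, slot: int) -> np.ndarray:
        """(4, 3) vertex array of a 1-based slot (may contain NaN)."""
        if not 1 <= slot <= N_SLOTS:
            raise CloudSchemaError(f"marker slot {slot} outside 1..{N_SLOTS}")
        return self.vertices[slot - 1]

    def centroids(self) -> np.ndarray:
        """(138, 3) marker centroids; NaN rows for absent slots."""
        return self.vertices.mean(axis=1)

    def cap_mask(self) -> np.ndarray:
        mask = np.zeros(N_SLOTS, dtype=bool)
        mask[:N_CAP_MARKERS] = True
        return mask & self.present

    def copy(self, **changes: Any) -> "HeadCloud":
        """Deep copy with optional field overrides."""
        changes.setdefault("vertices", self.vertices.copy())
        changes.setdefault("present", self.present.copy())
        changes.setdefault("meta", dict(self.meta))
        return replace(self, **changes)
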