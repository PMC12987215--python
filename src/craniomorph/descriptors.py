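"""Origin-to-marker distance descriptors and labelled feature tables.

For every marker slot, the descriptor is the mean of the four
origin-to-vertex Euclidean distances after canonicalisation into the
sticker-anchored frame (alternatively the distance from the origin to
the quad centroid, via ``mode='distance_to_centroid'``).  Absent slots
carry NaN, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from craniomorph.cloud import MIN_PRESENT, N_SLOTS, HeadCloud
from craniomorph.errors import CloudSchemaError, CraniomorphError
from craniomorph import geometry

#: d001 ... d138
DESCRIPTOR_COLUMNS = [f"d{i:03d}" for i in range(1, N_SLOTS + 1)]
META_COLUMNS = ["cloud_id", "base_id", "label_code", "split"]

MODES = ("mean_of_distances", "distance_to_centroid")


@dataclass(frozen=True)
class DescriptorVector:
    """138-slot distance descriptor of one cloud."""

    values: np.ndarray  # (138,), NaN for absent slots
    presence: np.ndarray  # (138,), bool
    label_code: int
    cloud_id: str
    base_id: str

    def __post_init__(self) -> None:
        if self.values.shape != (N_SLOTS,) or self.presence.shape != (N_SLOTS,):
            raise CraniomorphError("descriptor vector must have 138 slots")

    @property
    def n_present(self) -> int:
        return int(self.presence.sum())


def extract_descriptors(cloud: HeadCloud, mode: str = "mean_of_distances") -> DescriptorVector:
    """Extract the 138-slot descriptor vector of one cloud.

    The cloud is canonicalised first, so descriptors are invariant
    under rigid motion of the input.
    """
    if mode not in MODES:
        raise CraniomorphError(f"unknown descriptor mode {mode!r}")
    if cloud.n_present < MIN_PRESENT:
        raise CloudSchemaError(
            f"cloud below marker minimum: {cloud.n_present} < {MIN_PRESENT}"
        )
    canon = geometry.canonicalize(cloud)
    if mode == "mean_of_distances":
        dists = np.linalg.norm(canon.vertices, axis=2)  # (138, 4)
        values = dists.mean(axis=1)
    else:
        values = np.linalg.norm(canon.centroids(), axis=1)
    values = np.where(canon.present, values, np.nan)
    return DescriptorVector(
        values=values,
        presence=canon.present.copy(),
        label_code=cloud.label_code,
        cloud_id=cloud.cloud_id,
        base_id=cloud.base_id,
    )


def build_feature_table(
    clouds: list[HeadCloud] | tuple[HeadCloud, ...], mode: str = "mean_of_distances"
) -> pd.DataFrame:
    """One labelled descriptor row per cloud.

    Columns: cloud_id, base_id, label_code, split (initially
    ``"unassigned"``), d001..d138 (NaN = missing slot).
    """
    if not clouds:
        raise CraniomorphError("build_feature_table requires at least one cloud")
    rows = [extract_descriptors(c, mode=mode) for c in clouds]
    ids = [r.cloud_id for r in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CraniomorphError(f"duplicate cloud_id(s): {dupes[:5]}")
    table = pd.DataFrame(
        np.vstack([r.values for r in rows]), columns=DESCRIPTOR_COLUMNS
    )
    table.insert(0, "cloud_id", ids)
    table.insert(1, "base_id", [r.base_id for r in rows])
    table.insert(2, "label_code", [r.label_code for r in rows])
    table.insert(3, "split", "unassigned")
    return table


def descriptor_count_histogram(table: pd.DataFrame) -> dict[int, int]:
    """{number of non-missing descriptors: row count} over a feature table."""
    counts = table[DESCRIPTOR_COLUMNS].notna().sum(axis=1)
    return counts.value_counts().sort_index(ascending=False).to_dict()
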