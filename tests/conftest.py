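"""Shared fixtures and independent brute-force oracles.

The oracles are deliberately written as plain-Python loops so they
stay independent of the vectorised implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from craniomorph import augment, descriptors, headgen
from craniomorph.cloud import (
    N_SLOTS,
    SLOT_REF_FRONT,
    SLOT_REF_LEFT,
    SLOT_REF_RIGHT,
    HeadCloud,
)

# ---------------------------------------------------------------------------
# Cloud builders
# ---------------------------------------------------------------------------


def make_cloud(class_label: str = "normocephaly", n_missing: int = 0, seed: int = 0,
               jitter_sd: float | None = None) -> HeadCloud:
    import dataclasses

    params = headgen.CLASS_DEFAULTS[class_label]
    if jitter_sd is not None:
        params = dataclasses.replace(params, jitter_sd=jitter_sd)
    return headgen.generate_base_cloud(params, n_missing=n_missing, seed=seed)


def cloud_with_refs(left, right, front, base: HeadCloud | None = None) -> HeadCloud:
    """A valid cloud whose reference sticker centroids sit at given points."""
    cloud = (base or make_cloud(seed=3)).copy()
    offsets = np.array([[-1.0, -1.0, 0], [1.0, -1.0, 0], [1.0, 1.0, 0], [-1.0, 1.0, 0]])
    for slot, center in (
        (SLOT_REF_LEFT, left),
        (SLOT_REF_RIGHT, right),
        (SLOT_REF_FRONT, front),
    ):
        cloud.vertices[slot - 1] = np.asarray(center, dtype=float) + offsets
    return cloud


def random_rigid_motion(rng: np.random.Generator):
    """A uniform-ish random rotation matrix and translation vector."""
    A = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(A)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-50, 50, size=3)
    return q, t


def apply_rigid(cloud: HeadCloud, R: np.ndarray, t: np.ndarray) -> HeadCloud:
    out = cloud.copy()
    flat = out.vertices.reshape(-1, 3)
    out.vertices = (flat @ R.T + t).reshape(out.vertices.shape)
    return out


# ---------------------------------------------------------------------------
# Brute-force oracles (plain loops, no vectorisation)
# ---------------------------------------------------------------------------


def oracle_centroid(vertices) -> list[float]:
    sums = [0.0, 0.0, 0.0]
    for v in vertices:
        for k in range(3):
            sums[k] += float(v[k])
    return [s / 4.0 for s in sums]


def oracle_descriptors(cloud: HeadCloud) -> list[float]:
    """Loop-based re-derivation of the 138 mean origin-to-vertex distances."""
    # frame from sticker centroids, scalar arithmetic only
    L = oracle_centroid(cloud.marker_vertices(SLOT_REF_LEFT))
    R = oracle_centroid(cloud.marker_vertices(SLOT_REF_RIGHT))
    F = oracle_centroid(cloud.marker_vertices(SLOT_REF_FRONT))
    origin = [(L[k] + R[k]) / 2.0 for k in range(3)]
    ex = [R[k] - L[k] for k in range(3)]
    nx = math.sqrt(sum(c * c for c in ex))
    ex = [c / nx for c in ex]
    ant = [F[k] - origin[k] for k in range(3)]
    dot = sum(ant[k] * ex[k] for k in range(3))
    ey = [ant[k] - dot * ex[k] for k in range(3)]
    ny = math.sqrt(sum(c * c for c in ey))
    ey = [c / ny for c in ey]
    ez = [
        ex[1] * ey[2] - ex[2] * ey[1],
        ex[2] * ey[0] - ex[0] * ey[2],
        ex[0] * ey[1] - ex[1] * ey[0],
    ]
    values = []
    for slot in range(1, N_SLOTS + 1):
        if not cloud.present[slot - 1]:
            values.append(float("nan"))
            continue
        total = 0.0
        for v in cloud.marker_vertices(slot):
            rel = [float(v[k]) - origin[k] for k in range(3)]
            loc = [
                sum(rel[k] * ex[k] for k in range(3)),
                sum(rel[k] * ey[k] for k in range(3)),
                sum(rel[k] * ez[k] for k in range(3)),
            ]
            total += math.sqrt(sum(c * c for c in loc))
        values.append(total / 4.0)
    return values


def oracle_pairwise_distances(cloud: HeadCloud) -> list[float]:
    """All pairwise centroid distances between present markers (sorted slots)."""
    cents = []
    for slot in range(1, N_SLOTS + 1):
        if cloud.present[slot - 1]:
            cents.append(oracle_centroid(cloud.marker_vertices(slot)))
    out = []
    for i in range(len(cents)):
        for j in range(i + 1, len(cents)):
            out.append(
                math.sqrt(sum((cents[i][k] - cents[j][k]) ** 2 for k in range(3)))
            )
    return out


def oracle_extents_index(cloud: HeadCloud) -> float:
    """Cephalic index by scalar scan over canonical cap centroids."""
    from craniomorph import geometry

    canon = geometry.canonicalize(cloud)
    xmin = ymin = float("inf")
    xmax = ymax = -float("inf")
    for slot in range(1, 136):
        if not canon.present[slot - 1]:
            continue
        c = oracle_centroid(canon.marker_vertices(slot))
        xmin, xmax = min(xmin, c[0]), max(xmax, c[0])
        ymin, ymax = min(ymin, c[1]), max(ymax, c[1])
    return (xmax - xmin) / (ymax - ymin) * 100.0


# ---------------------------------------------------------------------------
# Session-scoped heavy fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def default_cohort():
    return headgen.generate_cohort(headgen.CohortPlan(seed=5))


@pytest.fixture(scope="session")
def augmented_cohort(default_cohort):
    return augment.augment_cohort(
        default_cohort, augment.ScalePlan(seed=3), augment.NoiseSpec(seed=11)
    )


@pytest.fixture(scope="session")
def feature_table(augmented_cohort):
    return descriptors.build_feature_table(augmented_cohort)


@pytest.fixture(scope="session")
def small_search_data(feature_table):
    """Stratified 60-row subsample for fit-count checks (size-invariant)."""
    from craniomorph.descriptors import DESCRIPTOR_COLUMNS

    rng = np.random.default_rng(0)
    idx = []
    for _, grp in feature_table.groupby("label_code"):
        idx.extend(rng.choice(grp.index, size=10, replace=False))
    sub = feature_table.loc[idx]
    X = sub[DESCRIPTOR_COLUMNS]
    X = X.fillna(X.mean()).to_numpy()
    y = sub["label_code"].to_numpy()
    return X, y
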