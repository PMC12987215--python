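"""Parametric generator of synthetic infant-head marker clouds.

The head surface is a superellipsoid in the canonical frame (x lateral,
y anterior, z vertical; tragus plane at z = 0), optionally deformed by
a posterior-quadrant shear (asymmetric flattening) or an anterior
linear taper (triangular forehead).  135 cap markers are placed on a
quasi-uniform Fibonacci lattice restricted to the hemisphere above the
tragus plane; each marker is a 7 mm tangent-plane square (4 vertices).
The three reference stickers sit at the lateral tragus points and the
anterior midline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from craniomorph.cloud import (
    CLASSES,
    MAX_MISSING,
    N_CAP_MARKERS,
    N_SLOTS,
    SLOT_REF_FRONT,
    SLOT_REF_LEFT,
    SLOT_REF_RIGHT,
    HeadCloud,
)
from craniomorph.errors import CloudSchemaError, CraniomorphError
from craniomorph import geometry

#: Side length of the square coded markers (mm).
MARKER_SIZE_MM = 7.0

#: Fraction of the anteroposterior semi-axis over which the anterior
#: taper acts (the front 40 % of total head length).
_TAPER_ONSET = 0.2  # y/length_ap above which the taper ramps in


@dataclass(frozen=True)
class ShapeParams:
    """Geometric parameters of one head-shape class.

    Semi-axes are in mm; ``squareness`` is the superellipsoid exponent;
    ``shear_asym`` shears the posterior quadrant laterally
    (plagiocephaly); ``frontal_taper`` narrows the anterior head
    linearly (trigonocephaly); ``jitter_sd`` is the per-cloud Gaussian
    variation of each semi-axis.
    """

    class_label: str
    length_ap: float
    width_ml: float
    height: float
    squareness: float = 2.5
    shear_asym: float = 0.0
    frontal_taper: float = 0.0
    jitter_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise CraniomorphError(f"unknown class label {self.class_label!r}")
        if min(self.length_ap, self.width_ml, self.height) <= 0:
            raise CraniomorphError("all semi-axes must be positive")
        if self.squareness <= 0:
            raise CraniomorphError("squareness must be positive")
        if self.jitter_sd < 0:
            raise CraniomorphError("jitter_sd must be non-negative")


#: Class default geometry.  Chosen so the cephalic index of the
#: defaults lands in the normative band of each class (brachycephaly
#: > 90, dolichocephaly < 75, normocephaly in [75, 90]) and the
#: towering height/length ratio strictly exceeds every other class.
CLASS_DEFAULTS: dict[str, ShapeParams] = {
    "brachycephaly": ShapeParams("brachycephaly", length_ap=85.0, width_ml=82.0, height=72.0),
    "dolichocephaly": ShapeParams("dolichocephaly", length_ap=105.0, width_ml=72.0, height=70.0),
    "normocephaly": ShapeParams("normocephaly", length_ap=95.0, width_ml=78.0, height=70.0),
    "plagiocephaly": ShapeParams(
        "plagiocephaly", length_ap=95.0, width_ml=78.0, height=70.0, shear_asym=0.25
    ),
    "towering": ShapeParams("towering", length_ap=92.0, width_ml=76.0, height=95.0),
    "trigonocephaly": ShapeParams(
        "trigonocephaly", length_ap=96.0, width_ml=77.0, height=70.0, frontal_taper=0.35
    ),
}

#: Default per-class base-cloud counts (60 in total).
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "brachycephaly": 10,
    "dolichocephaly": 11,
    "normocephaly": 5,
    "plagiocephaly": 9,
    "towering": 13,
    "trigonocephaly": 12,
}

#: Default per-class histogram of present-marker (descriptor) counts:
#: {descriptor_count: number of base clouds}.
DEFAULT_DROPOUT_HISTOGRAM: dict[str, dict[int, int]] = {
    "brachycephaly": {138: 3, 136: 2, 135: 3, 133: 1, 132: 1},
    "dolichocephaly": {138: 1, 137: 1, 136: 3, 135: 2, 134: 2, 133: 2},
    "normocephaly": {138: 3, 136: 2},
    "plagiocephaly": {138: 3, 136: 1, 134: 3, 133: 2},
    "towering": {138: 3, 137: 2, 136: 3, 135: 3, 134: 2},
    "trigonocephaly": {138: 5, 137: 1, 136: 2, 134: 3, 131: 1},
}


@dataclass(frozen=True)
class CohortPlan:
    """How many base clouds to generate per class and with which dropout."""

    class_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    dropout_histogram: Mapping[str, Mapping[int, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DROPOUT_HISTOGRAM.items()}
    )
    seed: int = 0

    def validate(self) -> None:
        for cls, count in self.class_counts.items():
            if cls not in CLASSES:
                raise CraniomorphError(f"unknown class {cls!r} in plan")
            if count < 0:
                raise CraniomorphError("class counts must be non-negative")
            hist = self.dropout_histogram.get(cls, {})
            if sum(hist.values()) != count:
                raise CraniomorphError(
                    f"dropout histogram for {cls} sums to {sum(hist.values())}, "
                    f"expected {count}"
                )
            for desc_count in hist:
                if not (N_SLOTS - MAX_MISSING) <= desc_count <= N_SLOTS:
                    raise CraniomorphError(
                        f"descriptor count {desc_count} outside "
                        f"[{N_SLOTS - MAX_MISSING}, {N_SLOTS}]"
                    )

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())


# ---------------------------------------------------------------------------
# Superellipsoid surface
# ---------------------------------------------------------------------------


def _implicit(params: ShapeParams, points: np.ndarray) -> np.ndarray:
    """Superellipsoid implicit function; zero on the (undeformed) surface."""
    p = params.squareness
    pts = np.atleast_2d(points)
    a, b, c = params.width_ml, params.length_ap, params.height
    return (
        np.abs(pts[:, 0] / a) ** p
        + np.abs(pts[:, 1] / b) ** p
        + np.abs(pts[:, 2] / c) ** p
        - 1.0
    )


def _deform(params: ShapeParams, points: np.ndarray) -> np.ndarray:
    """Apply class-specific shear/taper to canonical-frame points."""
    pts = np.atleast_2d(points).astype(float).copy()
    if params.shear_asym != 0.0:
        posterior = pts[:, 1] < 0
        pts[posterior, 0] += params.shear_asym * pts[posterior, 1]
    if params.frontal_taper != 0.0:
        t = pts[:, 1] / params.length_ap
        ramp = np.clip((t - _TAPER_ONSET) / (1.0 - _TAPER_ONSET), 0.0, None)
        pts[:, 0] *= 1.0 - params.frontal_taper * ramp
    return pts


def _undeform(params: ShapeParams, points: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_deform` (both maps leave y and z unchanged)."""
    pts = np.atleast_2d(points).astype(float).copy()
    if params.frontal_taper != 0.0:
        t = pts[:, 1] / params.length_ap
        ramp = np.clip((t - _TAPER_ONSET) / (1.0 - _TAPER_ONSET), 0.0, None)
        pts[:, 0] /= 1.0 - params.frontal_taper * ramp
    if params.shear_asym != 0.0:
        posterior = pts[:, 1] < 0
        pts[posterior, 0] -= params.shear_asym * pts[posterior, 1]
    return pts


def surface_residual(params: ShapeParams, points: np.ndarray) -> np.ndarray:
    """Signed distance proxy (mm) of points to the deformed head surface.

    Points are pulled back through the inverse deformation and measured
    radially against the analytic superellipsoid: the residual is the
    distance between the point's pull-back and its radial projection
    onto the surface, signed by the implicit function.
    """
    pts = _undeform(params, points)
    norms = np.linalg.norm(pts, axis=1)
    unit = pts / np.where(norms > 0, norms, 1.0)[:, None]
    r_surface = _radial_scale(params, unit)
    return norms - r_surface


def _radial_scale(params: ShapeParams, directions: np.ndarray) -> np.ndarray:
    """Distance from the origin to the superellipsoid along unit directions."""
    p = params.squareness
    a, b, c = params.width_ml, params.length_ap, params.height
    d = np.atleast_2d(directions)
    s = (
        np.abs(d[:, 0] / a) ** p
        + np.abs(d[:, 1] / b) ** p
        + np.abs(d[:, 2] / c) ** p
    )
    return s ** (-1.0 / p)


def _surface_normal(params: ShapeParams, points: np.ndarray) -> np.ndarray:
    """Outward unit normal of the undeformed superellipsoid at surface points."""
    p = params.squareness
    a, b, c = params.width_ml, params.length_ap, params.height
    pts = np.atleast_2d(points)
    grad = np.empty_like(pts)
    for j, ax in enumerate((a, b, c)):
        u = pts[:, j] / ax
        grad[:, j] = (p / ax) * np.sign(u) * np.abs(u) ** (p - 1)
    n = np.linalg.norm(grad, axis=1, keepdims=True)
    return grad / n


def _fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the upper hemisphere (z >= 0)."""
    i = np.arange(n)
    z = (i + 0.5) / n  # in (0, 1): strictly above the tragus plane
    phi = i * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _tangent_quad(center: np.ndarray, normal: np.ndarray, size: float) -> np.ndarray:
    """4 ordered vertices of a size x size square in the tangent plane."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(normal, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    h = size / 2.0
    return np.array(
        [
            center - h * t1 - h * t2,
            center + h * t1 - h * t2,
            center + h * t1 + h * t2,
            center - h * t1 + h * t2,
        ]
    )


# ---------------------------------------------------------------------------
# Cloud generation
# ---------------------------------------------------------------------------


def _jittered(params: ShapeParams, rng: np.random.Generator) -> ShapeParams:
    if params.jitter_sd == 0:
        return params
    axes = np.array([params.length_ap, params.width_ml, params.height])
    jitter = rng.normal(0.0, params.jitter_sd, size=3)
    # keep semi-axes safely positive even under extreme draws
    axes = np.maximum(axes + jitter, 0.5 * axes)
    return replace(params, length_ap=axes[0], width_ml=axes[1], height=axes[2])


def generate_base_cloud(
    params: ShapeParams,
    n_missing: int = 0,
    seed: int = 0,
    cloud_id: str | None = None,
) -> HeadCloud:
    """Generate one synthetic marker cloud.

    ``n_missing`` cap markers (chosen at random) are flagged absent;
    the three reference stickers are always present.  Deterministic for
    a given ``(params, n_missing, seed)``.
    """
    if not 0 <= n_missing <= MAX_MISSING:
        raise CraniomorphError(
            f"n_missing = {n_missing} would go below minimum marker count "
            f"({N_SLOTS - MAX_MISSING})"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    eff = _jittered(params, rng)

    directions = _fibonacci_directions(N_CAP_MARKERS)
    centers = directions * _radial_scale(eff, directions)[:, None]
    normals = _surface_normal(eff, centers)

    vertices = np.full((N_SLOTS, 4, 3), np.nan)
    for i in range(N_CAP_MARKERS):
        vertices[i] = _tangent_quad(centers[i], normals[i], MARKER_SIZE_MM)

    # Reference stickers: anterior midline and the two lateral tragus points.
    ref_specs = {
        SLOT_REF_FRONT: (np.array([0.0, eff.length_ap, 0.0]), np.array([0.0, 1.0, 0.0])),
        SLOT_REF_LEFT: (np.array([-eff.width_ml, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0])),
        SLOT_REF_RIGHT: (np.array([eff.width_ml, 0.0, 0.0]), np.array([1.0, 0.0, 0.0])),
    }
    for slot, (center, normal) in ref_specs.items():
        vertices[slot - 1] = _tangent_quad(center, normal, MARKER_SIZE_MM)

    flat = vertices.reshape(-1, 3)
    vertices = _deform(eff, flat).reshape(vertices.shape)

    present = np.ones(N_SLOTS, dtype=bool)
    if n_missing:
        dropped = rng.choice(N_CAP_MARKERS, size=n_missing, replace=False)
        present[dropped] = False
        vertices[dropped] = np.nan

    cid = cloud_id or f"{params.class_label[:6]}-s{seed}"
    return HeadCloud(
        cloud_id=cid,
        base_id=cid,
        class_label=params.class_label,
        vertices=vertices,
        present=present,
        provenance="original",
        meta={"shape_params": eff},
    )


def generate_cohort(plan: CohortPlan | None = None) -> list[HeadCloud]:
    """Generate the planned base cohort, honouring the dropout histogram exactly."""
    plan = plan or CohortPlan()
    plan.validate()
    root = np.random.SeedSequence(plan.seed)
    clouds: list[HeadCloud] = []
    for cls in CLASSES:
        count = plan.class_counts.get(cls, 0)
        if count == 0:
            continue
        hist = plan.dropout_histogram[cls]
        # deterministic order: descriptor counts descending
        n_missing_list = [
            N_SLOTS - desc for desc in sorted(hist, reverse=True) for _ in range(hist[desc])
        ]
        child_seeds = root.spawn(1)[0]  # keep per-class stream stable
        seeds = np.random.default_rng(child_seeds).integers(0, 2**63 - 1, size=count)
        for idx, (n_missing, s) in enumerate(zip(n_missing_list, seeds)):
            clouds.append(
                generate_base_cloud(
                    CLASS_DEFAULTS[cls],
                    n_missing=n_missing,
                    seed=int(s),
                    cloud_id=f"{cls[:6]}-{idx:02d}",
                )
            )
    return clouds


def cephalic_index(cloud: HeadCloud) -> float:
    """Maximum mediolateral extent / maximum anteroposterior extent x 100.

    Computed over cap-marker centroids in the canonical sticker frame,
    so the value is invariant under rigid motion of the whole cloud.
    """
    canon = geometry.canonicalize(cloud)
    cents = canon.centroids()[canon.cap_mask()]
    if cents.shape[0] < 3:
        raise CloudSchemaError("cephalic index needs at least 3 present cap markers")
    width = cents[:, 0].max() - cents[:, 0].min()
    length = cents[:, 1].max() - cents[:, 1].min()
    return float(width / length * 100.0)


def iter_class_params(jitter_sd: float | None = None) -> Iterator[ShapeParams]:
    """Class default parameters, optionally with an overridden jitter."""
    for cls in CLASSES:
        p = CLASS_DEFAULTS[cls]
        yield p if jitter_sd is None else replace(p, jitter_sd=jitter_sd)
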