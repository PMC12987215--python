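"""Reference frame from the three stickers and basic marker geometry.

The canonical frame is anchored on the three reference stickers: the
origin is the midpoint of the left and right preauricular sticker
centroids, the lateral (+x) axis points left -> right, the anterior
(+y) axis is the front-sticker direction orthogonalised against the
lateral axis, and the vertical (+z) axis completes a right-handed
triad.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from craniomorph.cloud import (
    SLOT_REF_FRONT,
    SLOT_REF_LEFT,
    SLOT_REF_RIGHT,
    HeadCloud,
)
from craniomorph.errors import DegenerateFrameError, FrameError, MissingMarkerError

_ORTHO_TOL = 1e-9
_DEGENERACY_TOL = 1e-8


@dataclass(frozen=True)
class ReferenceFrame:
    """Rigid frame: ``p_local = rotation.T @ (p_world - origin)``.

    ``rotation`` columns are the lateral, anterior and vertical axis
    directions expressed in world coordinates.
    """

    origin: np.ndarray  # (3,)
    rotation: np.ndarray  # (3, 3), orthonormal, det +1

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise FrameError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise FrameError("rotation matrix is not right-handed")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates into the canonical frame."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.rotation

    def to_world(self, points: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_local`."""
        return np.asarray(points, dtype=float) @ self.rotation.T + self.origin


def marker_centroid(vertices: np.ndarray) -> np.ndarray:
    """Arithmetic mean of a marker's 4 vertices.

    Raises
    ------
    MissingMarkerError
        If the vertices contain NaN (absent marker).
    """
    v = np.asarray(vertices, dtype=float)
    if v.shape != (4, 3):
        raise MissingMarkerError(f"expected (4, 3) vertex array, got shape {v.shape}")
    if not np.isfinite(v).all():
        raise MissingMarkerError("missing marker: vertices are not finite")
    return v.mean(axis=0)


def _ref_centroid(cloud: HeadCloud, slot: int) -> np.ndarray:
    if not cloud.present[slot - 1]:
        raise FrameError(f"frame undefined: reference sticker slot {slot} missing")
    return marker_centroid(cloud.marker_vertices(slot))


def establish_frame(cloud: HeadCloud) -> ReferenceFrame:
    """Build the canonical sticker-anchored frame of a cloud.

    Raises
    ------
    FrameError
        If a reference sticker is absent.
    DegenerateFrameError
        If the three sticker centroids are (near-)collinear.
    """
    front = _ref_centroid(cloud, SLOT_REF_FRONT)
    left = _ref_centroid(cloud, SLOT_REF_LEFT)
    right = _ref_centroid(cloud, SLOT_REF_RIGHT)

    origin = 0.5 * (left + right)
    lateral = right - left
    norm_lat = np.linalg.norm(lateral)
    if norm_lat < _DEGENERACY_TOL:
        raise DegenerateFrameError("left and right stickers coincide")
    ex = lateral / norm_lat

    anterior = front - origin
    anterior = anterior - (anterior @ ex) * ex  # Gram-Schmidt against lateral
    norm_ant = np.linalg.norm(anterior)
    if norm_ant < _DEGENERACY_TOL:
        raise DegenerateFrameError("reference stickers are collinear")
    ey = anterior / norm_ant

    ez = np.cross(ex, ey)
    R = np.column_stack([ex, ey, ez])
    # Re-orthonormalise to the stated tolerance.
    u, _, vt = np.linalg.svd(R)
    R = u @ vt
    assert np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL)
    return ReferenceFrame(origin=origin, rotation=R)


def canonicalize(cloud: HeadCloud, frame: ReferenceFrame | None = None) -> HeadCloud:
    """Express all vertices in the sticker-anchored canonical frame."""
    if frame is None:
        frame = establish_frame(cloud)
    out = cloud.copy()
    flat = out.vertices.reshape(-1, 3)
    out.vertices = frame.to_local(flat).reshape(out.vertices.shape)
    return out


def preauricular_distance(cloud: HeadCloud) -> float:
    """Euclidean distance between left and right preauricular sticker centroids (mm)."""
    left = _ref_centroid(cloud, SLOT_REF_LEFT)
    right = _ref_centroid(cloud, SLOT_REF_RIGHT)
    d = float(np.linalg.norm(right - left))
    if d <= 0:
        raise FrameError("degenerate preauricular distance")
    return d
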