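"""Frankfurt-horizontal-plane alignment.

Each scan is rigidly rotated so that the plane fitted through the two
orbitale and two porion landmarks (LOr, ROr, LPAE, RPAE) becomes the
axial plane, with the inter-porion axis fixing the in-plane (yaw)
orientation. Four points over-determine a plane, so a total-least-squares
fit is used and its rms residual is reported as a QC metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import LandmarkSet, VolumeImage

__all__ = [
    "RigidTransform",
    "FH_LANDMARKS",
    "fit_fh_plane",
    "build_fh_transform",
    "resample_to_fh",
    "align_scan",
]

FH_LANDMARKS = ("LOr", "ROr", "LPAE", "RPAE")


@dataclass
class RigidTransform:
    """x' = rotation @ x + translation, with rotation in SO(3)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal within 1e-8")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (self.rotation @ pts.T).T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """The transform equivalent to applying ``first`` then ``self``."""
        return RigidTransform(
            self.rotation @ first.rotation,
            self.rotation @ first.translation + self.translation,
        )

    @property
    def angle_deg(self) -> float:
        """Rotation angle of the axis-angle decomposition, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def fit_fh_plane(landmarks: LandmarkSet) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares plane through LOr, ROr, LPAE, RPAE.

    Returns ``(unit normal, centroid, rms residual mm)`` with the normal
    oriented toward +z (superior).
    """
    pts = landmarks.array(FH_LANDMARKS)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=True)
    if s[1] < 1e-9 * max(1.0, s[0]):
        raise ValueError("Frankfurt landmarks are collinear or coincident")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    rms = float(s[2] / np.sqrt(len(pts)))
    return normal, centroid, rms


def build_fh_transform(landmarks: LandmarkSet) -> RigidTransform:
    """Rigid transform taking the scan into the Frankfurt frame.

    The fitted plane normal maps to +z; the LPAE->RPAE axis (projected
    onto the plane) maps to +x; the Frankfurt-landmark centroid maps to
    the origin.
    """
    normal, centroid, _ = fit_fh_plane(landmarks)
    porion = landmarks["RPAE"] - landmarks["LPAE"]
    in_plane = porion - np.dot(porion, normal) * normal
    n = np.linalg.norm(in_plane)
    if n < 1e-9:
        raise ValueError("porion axis is parallel to the plane normal")
    e1 = in_plane / n
    e3 = normal
    e2 = np.cross(e3, e1)
    rotation = np.stack([e1, e2, e3])
    return RigidTransform(rotation, -rotation @ centroid)


def resample_to_fh(
    volume: VolumeImage,
    transform: RigidTransform,
    fill: float = 40.0,
    is_mask: bool = False,
) -> VolumeImage:
    """Resample onto an axis-aligned grid in the Frankfurt frame.

    Trilinear interpolation for HU volumes, nearest-neighbour for masks;
    the output grid spans the transformed bounding box at the input
    spacing and out-of-field voxels take ``fill``.
    """
    shape = np.asarray(volume.data.shape)
    corners = np.array([[i, j, k] for i in (0, shape[0] - 1)
                        for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)], dtype=float)
    world = transform.apply(volume.index_to_world(corners))
    lo, hi = world.min(axis=0), world.max(axis=0)
    spacing = volume.spacing.copy()
    out_shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    origin = lo
    if np.prod(out_shape) == 0:
        raise ValueError("empty overlap after transformation")
    # output index -> source index affine
    Rt = transform.rotation.T
    S_in = np.diag(1.0 / volume.spacing)
    A = S_in @ volume.direction.T @ Rt @ np.diag(spacing)
    b = S_in @ volume.direction.T @ (Rt @ (origin - transform.translation) - volume.origin)
    order = 0 if is_mask else 1
    out = ndimage.affine_transform(
        np.asarray(volume.data, dtype=volume.data.dtype if is_mask else np.float32),
        A,
        offset=b,
        output_shape=tuple(out_shape),
        order=order,
        mode="constant",
        cval=fill,
        prefilter=False,
    )
    return VolumeImage(out, spacing, origin, np.eye(3))


def align_scan(
    volume: VolumeImage,
    landmarks: LandmarkSet,
    fill: float = 40.0,
) -> tuple[VolumeImage, LandmarkSet, RigidTransform, dict]:
    """Align one scan: returns (aligned volume, aligned landmarks, transform, QC).

    QC reports the plane-fit rms residual (mm) and the rotation angle (deg).
    """
    transform = build_fh_transform(landmarks)
    _, _, rms = fit_fh_plane(landmarks)
    aligned = resample_to_fh(volume, transform, fill=fill)
    moved = landmarks.transformed(transform.apply)
    qc = {"fh_plane_rms_mm": rms, "rotation_angle_deg": transform.angle_deg}
    return aligned, moved, transform, qc
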