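"""Volumes, landmark files, and cohort/metric tables.

Conventions used throughout the package:

* World coordinates are RAS millimetres (+x patient-right, +y anterior,
  +z superior); an axial slice is a constant-z plane.
* Voxel indexing is 0-based along (x, y, z) and a voxel's world position
  is its centre: ``world = origin + direction @ (spacing * ijk)``.
* Areas are reported in mm^2 and volumes in cm^3 at the table boundary;
  internal computation is in mm^3.

Files in LPS dialects (SimpleITK/NRRD, Slicer markup JSON declaring
``"coordinateSystem": "LPS"``) are converted at the boundary by flipping
the x and y world axes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "VolumeImage",
    "LandmarkSet",
    "MissingLandmarkError",
    "REQUIRED_LANDMARKS",
    "METRIC_COLUMNS",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "read_metrics",
    "write_metrics",
    "validate_cohort_table",
]

_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0])


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------


@dataclass
class VolumeImage:
    """A 3D scalar grid (Hounsfield units or a binary mask) in world mm.

    ``data`` is indexed ``[i, j, k]`` along world (x, y, z) when
    ``direction`` is the identity; ``direction``'s columns are the world
    directions of the voxel axes.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume grid must be a non-empty 3D array")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive values")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix is not orthonormal within 1e-6")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def is_canonical(self, atol: float = 1e-6) -> bool:
        return bool(np.allclose(self.direction, np.eye(3), atol=atol))

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return self.origin + (self.direction @ (self.spacing * ijk).T).T

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index of a world position."""
        xyz = np.asarray(xyz, dtype=float)
        rel = (self.direction.T @ (xyz - self.origin).T).T
        return rel / self.spacing

    def z_levels(self) -> np.ndarray:
        """World z of each axial slice centre (canonical orientation only)."""
        if not self.is_canonical():
            raise ValueError("z_levels requires a canonically oriented volume")
        return self.origin[2] + self.spacing[2] * np.arange(self.data.shape[2])

    def like(self, data: np.ndarray) -> "VolumeImage":
        """A new volume on this grid with different voxel data."""
        if data.shape != self.data.shape:
            raise ValueError("data shape must match the source grid")
        return VolumeImage(data, self.spacing.copy(), self.origin.copy(), self.direction.copy())


def _normalize_orientation(vol: VolumeImage) -> VolumeImage:
    """Reorient to the internal frame when ``direction`` is a signed permutation.

    Volumes stored e.g. inferior-to-superior flipped come out with identical
    world-coordinate content. Non-axis-aligned (but orthonormal) direction
    matrices are left untouched; the alignment stage resamples them anyway.
    """
    D = vol.direction
    P = np.rint(D)
    if not np.allclose(D, P, atol=1e-6) or not np.allclose(np.abs(P).sum(axis=0), 1):
        return vol
    # voxel axis feeding each world axis, and its sign
    perm = [int(np.argmax(np.abs(P[a]))) for a in range(3)]
    signs = [int(P[a, perm[a]]) for a in range(3)]
    data = np.transpose(vol.data, perm)
    spacing = vol.spacing[perm]
    first_index = np.zeros(3)
    for a in range(3):
        if signs[a] < 0:
            data = np.flip(data, axis=a)
            first_index[perm[a]] = vol.data.shape[perm[a]] - 1
    origin = vol.index_to_world(first_index)
    return VolumeImage(np.ascontiguousarray(data), spacing, origin, np.eye(3))


def read_volume(path: str | Path) -> VolumeImage:
    """Read an NRRD/MetaImage/NIfTI volume into the internal RAS frame.

    Axis-aligned storage orders (flips/permutations) are normalized so the
    grid runs +x/+y/+z; the world content is unchanged.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        aff = np.asarray(img.affine, dtype=float)
        lin = aff[:3, :3]
        spacing = np.linalg.norm(lin, axis=0)
        if np.any(spacing <= 0):
            raise ValueError(f"non-positive spacing in {path}")
        direction = lin / spacing
        data = np.asarray(img.dataobj)
        origin = aff[:3, 3]
    else:
        img = sitk.ReadImage(str(path))
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        spacing = np.asarray(img.GetSpacing(), dtype=float)
        origin = _LPS_TO_RAS @ np.asarray(img.GetOrigin(), dtype=float)
        direction = _LPS_TO_RAS @ np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    if data.size == 0:
        raise ValueError(f"empty volume: {path}")
    if not np.allclose(direction @ direction.T, np.eye(3), atol=1e-6):
        raise ValueError(f"non-orthogonal direction matrix in {path}")
    vol = VolumeImage(data, spacing, origin, direction)
    return _normalize_orientation(vol)


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    """Write NRRD/MetaImage (via SimpleITK, LPS on disk) or NIfTI (RAS)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        aff = np.eye(4)
        aff[:3, :3] = vol.direction * vol.spacing
        aff[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(np.asarray(vol.data), aff), str(path))
        return
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(_LPS_TO_RAS @ vol.origin))
    img.SetDirection(tuple((_LPS_TO_RAS @ vol.direction).ravel()))
    sitk.WriteImage(img, str(path), useCompression=False)


# --------------------------------------------------------------------------
# landmarks
# --------------------------------------------------------------------------

#: The eight fiducials a full analysis requires: orbitale and porion pairs
#: (Frankfurt plane), posterior nasal spine, uvula tip, epiglottis tip/bottom.
REQUIRED_LANDMARKS = (
    "LOr",
    "ROr",
    "RPAE",
    "LPAE",
    "SNP",
    "UVU",
    "EpiTip",
    "EpiBot",
)


class MissingLandmarkError(KeyError):
    pass


@dataclass
class LandmarkSet:
    """Named fiducials in world (RAS) millimetres."""

    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for label, pos in self.positions.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (3,) or not np.all(np.isfinite(pos)):
                raise ValueError(f"landmark {label!r} has a non-finite position")
            clean[str(label)] = pos
        self.positions = clean

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.positions[label]
        except KeyError:
            raise MissingLandmarkError(f"missing landmark: {label}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def extra_labels(self) -> tuple[str, ...]:
        return tuple(k for k in self.positions if k not in REQUIRED_LANDMARKS)

    def require_full(self) -> None:
        for label in REQUIRED_LANDMARKS:
            if label not in self.positions:
                raise MissingLandmarkError(f"missing landmark: {label}")

    def transformed(self, fn) -> "LandmarkSet":
        return LandmarkSet({k: fn(v) for k, v in self.positions.items()})

    def array(self, labels) -> np.ndarray:
        return np.stack([self[label] for label in labels])


def read_landmarks(path: str | Path, require_all: bool = True) -> LandmarkSet:
    """Read a markup-JSON or ``label,x,y,z`` CSV landmark file.

    Markup JSON may be either the Slicer-style document (``{"markups":
    [{"coordinateSystem": ..., "controlPoints": [...]}]}``) or a bare array
    of ``{"label": ..., "position": [x, y, z]}`` (assumed RAS). LPS files
    are converted by flipping x and y.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        positions: dict[str, np.ndarray] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                positions[row["label"]] = np.array(
                    [float(row["x"]), float(row["y"]), float(row["z"])]
                )
    else:
        doc = json.loads(path.read_text())
        system = "RAS"
        if isinstance(doc, dict):
            markup = doc["markups"][0]
            system = str(markup.get("coordinateSystem", "LPS")).upper()
            points = markup["controlPoints"]
        else:
            points = doc
        positions = {p["label"]: np.asarray(p["position"], dtype=float) for p in points}
        if system == "LPS":
            positions = {k: _LPS_TO_RAS @ v for k, v in positions.items()}
        elif system != "RAS":
            raise ValueError(f"unsupported coordinate system {system!r} in {path}")
    lms = LandmarkSet(positions)
    if require_all:
        lms.require_full()
    return lms


def write_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "x", "y", "z"])
            for label, pos in lms.positions.items():
                writer.writerow([label, repr(float(pos[0])), repr(float(pos[1])), repr(float(pos[2]))])
        return
    doc = {
        "markups": [
            {
                "type": "Fiducial",
                "coordinateSystem": "RAS",
                "controlPoints": [
                    {"label": label, "position": [float(x) for x in pos]}
                    for label, pos in lms.positions.items()
                ],
            }
        ]
    }
    path.write_text(json.dumps(doc, indent=1))


# --------------------------------------------------------------------------
# cohort / metric tables
# --------------------------------------------------------------------------

#: Long-format cohort table columns with units embedded in the names.
METRIC_COLUMNS = (
    "patient_id",
    "protrusion_mm",
    "minCSA_mm2",
    "minCSA_region",
    "minCSA_z_mm",
    "meanCSA_naso_mm2",
    "meanCSA_oro_mm2",
    "meanCSA_hypo_mm2",
    "meanCSA_overall_mm2",
    "volume_naso_cm3",
    "volume_oro_cm3",
    "volume_hypo_cm3",
    "volume_total_cm3",
)

_KEY = ["patient_id", "protrusion_mm"]


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Enforce the long-format cohort contract.

    At most one row per (patient, protrusion); volume columns must carry a
    ``_cm3`` suffix and CSA columns ``_mm2`` — mixed-unit headers are a hard
    error, not a silent conversion.
    """
    for col in _KEY:
        if col not in table.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
    if table.duplicated(subset=_KEY).any():
        dup = table.loc[table.duplicated(subset=_KEY), _KEY].iloc[0]
        raise ValueError(
            f"duplicate (patient, protrusion) row: {tuple(dup)}"
        )
    for col in table.columns:
        low = col.lower()
        if low.startswith("volume") and not low.endswith("_cm3"):
            raise ValueError(f"volume column {col!r} must be in cm^3 (suffix _cm3)")
        if "csa" in low and low.endswith(("_mm3", "_cm3", "_cm2", "_m2")):
            raise ValueError(f"cross-sectional-area column {col!r} must be in mm^2")
    return table


def write_metrics(table: pd.DataFrame, path: str | Path) -> None:
    validate_cohort_table(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    return validate_cohort_table(pd.read_csv(path))
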