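"""Regional partition and cross-sectional-area / volume metrics.

The segmented airway is divided by the axial (z) levels of four landmarks
in the Frankfurt-aligned frame: nasopharynx (SNP down to UVU), oropharynx
(UVU down to EpiTip), hypopharynx (EpiTip down to EpiBot). Intervals are
half-open with the upper boundary inclusive to the superior region, and
the lowest interval closed at both ends, so every slice between EpiBot
and SNP is assigned exactly once.

minCSA is taken over the naso- and oropharynx only: a hypopharyngeal
minimum is not meaningful because the epiglottis is mobile and the
laryngeal cartilage collapsible. meanCSA is the arithmetic mean of the
slice areas of a region; the overall meanCSA averages over all three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LandmarkSet, VolumeImage

__all__ = [
    "RegionBounds",
    "AirwayMetrics",
    "REGIONS",
    "region_bounds",
    "csa_profile",
    "compute_metrics",
]

REGIONS = ("naso", "oro", "hypo")


@dataclass
class RegionBounds:
    """Axial landmark levels (mm) with z_SNP > z_UVU > z_EpiTip > z_EpiBot."""

    z_snp: float
    z_uvu: float
    z_epitip: float
    z_epibot: float

    def __post_init__(self) -> None:
        levels = (self.z_snp, self.z_uvu, self.z_epitip, self.z_epibot)
        if not all(np.isfinite(levels)):
            raise ValueError("non-finite landmark level")
        if not (self.z_snp > self.z_uvu > self.z_epitip > self.z_epibot):
            raise ValueError(
                "landmark levels must be ordered z_SNP > z_UVU > z_EpiTip > z_EpiBot "
                f"(got {levels})"
            )

    def region_of(self, z: float) -> str | None:
        """Region of an axial level, or None outside [z_EpiBot, z_SNP]."""
        if self.z_uvu < z <= self.z_snp:
            return "naso"
        if self.z_epitip < z <= self.z_uvu:
            return "oro"
        if self.z_epibot <= z <= self.z_epitip:
            return "hypo"
        return None

    def intervals(self) -> dict[str, tuple[float, float]]:
        return {
            "naso": (self.z_uvu, self.z_snp),
            "oro": (self.z_epitip, self.z_uvu),
            "hypo": (self.z_epibot, self.z_epitip),
        }


def region_bounds(landmarks: LandmarkSet) -> RegionBounds:
    """Region boundaries from aligned landmark z-levels."""
    return RegionBounds(
        z_snp=float(landmarks["SNP"][2]),
        z_uvu=float(landmarks["UVU"][2]),
        z_epitip=float(landmarks["EpiTip"][2]),
        z_epibot=float(landmarks["EpiBot"][2]),
    )


def csa_profile(mask: VolumeImage, bounds: RegionBounds) -> pd.DataFrame:
    """Per-slice cross-sectional areas of the airway mask.

    Returns a DataFrame with columns ``z_mm, area_mm2, region`` (one row
    per axial slice between EpiBot and SNP) and the slice spacing stored
    in ``.attrs["z_spacing_mm"]``. Slices with zero airway voxels inside
    the bounds contribute area 0: an obstructed level is a real level.
    """
    if not mask.is_canonical():
        raise ValueError("csa_profile expects a Frankfurt-aligned (canonical) mask")
    pixel_area = float(mask.spacing[0] * mask.spacing[1])
    counts = np.asarray(mask.data, dtype=bool).sum(axis=(0, 1))
    rows = []
    for k, z in enumerate(mask.z_levels()):
        region = bounds.region_of(float(z))
        if region is None:
            continue
        rows.append((float(z), float(counts[k]) * pixel_area, region))
    profile = pd.DataFrame(rows, columns=["z_mm", "area_mm2", "region"])
    profile.attrs["z_spacing_mm"] = float(mask.spacing[2])
    return profile


@dataclass
class AirwayMetrics:
    """minCSA, per-region meanCSA (mm^2) and volumes (cm^3) for one scan."""

    mincsa_mm2: float
    mincsa_z_mm: float
    mincsa_region: str
    meancsa_mm2: dict[str, float]
    meancsa_overall_mm2: float
    volume_cm3: dict[str, float]
    volume_total_cm3: float
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict[str, float | str]:
        return {
            "minCSA_mm2": self.mincsa_mm2,
            "minCSA_region": self.mincsa_region,
            "minCSA_z_mm": self.mincsa_z_mm,
            "meanCSA_naso_mm2": self.meancsa_mm2.get("naso", np.nan),
            "meanCSA_oro_mm2": self.meancsa_mm2.get("oro", np.nan),
            "meanCSA_hypo_mm2": self.meancsa_mm2.get("hypo", np.nan),
            "meanCSA_overall_mm2": self.meancsa_overall_mm2,
            "volume_naso_cm3": self.volume_cm3.get("naso", np.nan),
            "volume_oro_cm3": self.volume_cm3.get("oro", np.nan),
            "volume_hypo_cm3": self.volume_cm3.get("hypo", np.nan),
            "volume_total_cm3": self.volume_total_cm3,
        }


def compute_metrics(profile: pd.DataFrame, bounds: RegionBounds) -> AirwayMetrics:
    """Metrics from a slice-area profile.

    minCSA is the minimum over naso+oro slices (ties broken toward the
    most superior slice); region volume is sum(area) * z-spacing in cm^3;
    total volume is the sum over regions (exact, same voxel partition).
    A region with no slices is flagged missing, not reported as zero.
    """
    if profile.empty:
        raise ValueError("empty profile")
    dz = float(profile.attrs.get("z_spacing_mm", np.median(np.diff(np.sort(profile["z_mm"].unique())))))
    flags: list[str] = []

    no = profile[profile["region"].isin(("naso", "oro"))]
    if no.empty:
        raise ValueError("no naso/oropharyngeal slices inside the bounds")
    amin = no["area_mm2"].min()
    ties = no[no["area_mm2"] == amin]
    best = ties.loc[ties["z_mm"].idxmax()]

    meancsa: dict[str, float] = {}
    volume: dict[str, float] = {}
    for region in REGIONS:
        sub = profile[profile["region"] == region]
        if sub.empty:
            flags.append(f"region {region} has no slices")
            continue
        meancsa[region] = float(sub["area_mm2"].mean())
        volume[region] = float(sub["area_mm2"].sum() * dz) / 1000.0
    zero = int((profile["area_mm2"] == 0).sum())
    if zero:
        flags.append(f"{zero} zero-area slice(s) inside the bounds")
    return AirwayMetrics(
        mincsa_mm2=float(amin),
        mincsa_z_mm=float(best["z_mm"]),
        mincsa_region=str(best["region"]),
        meancsa_mm2=meancsa,
        meancsa_overall_mm2=float(profile["area_mm2"].mean()),
        volume_cm3=volume,
        volume_total_cm3=float(sum(volume.values())),
        flags=flags,
    )
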