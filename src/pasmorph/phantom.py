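"""Synthetic pharynx phantoms with analytic ground truth.

The cohort emulates a supine CT study of the posterior airway space under
mandibular protrusion (0/4/8 mm). Each patient's airway is a straight
vertical tube of circular cross-section whose area profile A(z) is
piecewise constant over the three pharyngeal regions plus a single smooth
constriction (a compact cos^2 dip), floored at a small positive area:

    A(z) = max(floor, level_r(z) - D(p) * cos^2(pi (z - c) / (2 w(p))))

* ``level_r = base + b_i + eps_ij + slope_r * p``: a per-patient random
  intercept b_i, a per-scan residual eps_ij, and a region-specific
  additive protrusion effect (mm^2 per mm of protrusion).
* The constriction sits in the nasopharynx for 92% of patients (in the
  oropharynx otherwise), so the minimum cross-sectional area localizes
  there at the study's observed rate.
* The constriction depth shrinks with protrusion at the rate needed to
  make the minCSA slope exactly the configured value, while its width
  grows to keep the depth x width integral constant — so regional mean
  areas and volumes keep exactly the injected regional slopes.

Ground-truth metrics are evaluated from the continuous profile in closed
form (elementary integrals of the cos^2 bump); the voxelizer renders the
same geometry onto a CT grid, applies a random head tilt to the volume
and all eight landmarks, and adds Gaussian HU noise.

Default calibration: the floored P0 minCSA mean equals 236.4 mm^2 and the
unfloored P0 total volume equals 24.0 cm^3; region lengths (30, 21.1,
29.4 mm) make the total-volume slope 1.61 cm^3/mm and the length-weighted
overall meanCSA slope 20.0 mm^2/mm given the regional slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .io import LandmarkSet, VolumeImage, validate_cohort_table

__all__ = [
    "PhantomSpec",
    "PatientParams",
    "ScanParams",
    "GroundTruth",
    "sample_cohort",
    "analytic_truth",
    "voxelize_phantom",
    "truth_table",
]

_TOTAL_SD_DEFAULT = 192.2  # P0 minCSA SD used for the default noise split


@dataclass
class PhantomSpec:
    """Geometry, effect sizes, and noise structure of the phantom cohort.

    ``base_area_mm2`` and ``constriction_depth_mm2`` default to None and
    are then solved at construction so that the expected (floored) P0
    minCSA equals ``target_mincsa_p0_mm2`` and the unfloored P0 total
    volume equals ``target_volume_p0_cm3``.
    """

    grid_shape: tuple[int, int, int] | None = None
    spacing_mm: tuple[float, float, float] = (0.76, 0.76, 0.9)
    airway_hu: float = -1000.0
    tissue_hu: float = 40.0
    noise_sd_hu: float = 20.0
    region_lengths_mm: tuple[float, float, float] = (30.0, 21.1, 29.4)  # naso, oro, hypo
    base_area_mm2: float | None = None
    constriction_depth_mm2: float | None = None
    constriction_halfwidth_mm: float = 6.0
    region_area_slopes_mm2_per_mm: tuple[float, float, float] = (21.9, 25.8, 13.9)
    mincsa_slope_mm2_per_mm: float = 24.9
    patient_sd_mm2: float = math.sqrt(0.7) * _TOTAL_SD_DEFAULT
    residual_sd_mm2: float = math.sqrt(0.3) * _TOTAL_SD_DEFAULT
    tilt_max_deg: float = 5.0
    missingness: tuple[float, float, float] = (48 / 50, 45 / 50, 37 / 50)
    protrusions_mm: tuple[float, ...] = (0.0, 4.0, 8.0)
    naso_constriction_prob: float = 0.92
    area_floor_mm2: float = 10.0
    target_mincsa_p0_mm2: float = 236.4
    target_volume_p0_cm3: float = 24.0
    p_radial_forearm: float = 0.48
    p_radiotherapy: float = 0.26
    stopbang_probs: tuple[float, float, float] = (0.74, 0.22, 0.04)  # low, moderate, high

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacings must be positive")
        if self.airway_hu >= self.tissue_hu:
            raise ValueError("airway HU must be below tissue HU")
        if any(l <= 0 for l in self.region_lengths_mm):
            raise ValueError("region lengths must be positive")
        if self.noise_sd_hu < 0 or self.patient_sd_mm2 < 0 or self.residual_sd_mm2 < 0:
            raise ValueError("noise SDs must be non-negative")
        if not all(0.0 <= m <= 1.0 for m in self.missingness):
            raise ValueError("retention probabilities must lie in [0, 1]")
        if not 0.0 <= self.naso_constriction_prob <= 1.0:
            raise ValueError("naso_constriction_prob must lie in [0, 1]")
        if self.base_area_mm2 is None or self.constriction_depth_mm2 is None:
            base, depth = calibrate_baseline(
                target_mincsa=self.target_mincsa_p0_mm2,
                target_volume_mm3=self.target_volume_p0_cm3 * 1000.0,
                level_sd=math.hypot(self.patient_sd_mm2, self.residual_sd_mm2),
                floor=self.area_floor_mm2,
                halfwidth=self.constriction_halfwidth_mm,
                total_length=self.total_length_mm,
            )
            if self.base_area_mm2 is None:
                self.base_area_mm2 = base
            if self.constriction_depth_mm2 is None:
                self.constriction_depth_mm2 = depth
        if self.constriction_depth_mm2 < 0:
            raise ValueError("constriction depth must be non-negative")

    # -- derived geometry (z runs 0 at EpiBot to total length at SNP) --

    @property
    def total_length_mm(self) -> float:
        return float(sum(self.region_lengths_mm))

    @property
    def z_epibot(self) -> float:
        return 0.0

    @property
    def z_epitip(self) -> float:
        return float(self.region_lengths_mm[2])

    @property
    def z_uvu(self) -> float:
        return float(self.region_lengths_mm[2] + self.region_lengths_mm[1])

    @property
    def z_snp(self) -> float:
        return self.total_length_mm

    def region_interval(self, region: str) -> tuple[float, float]:
        return {
            "naso": (self.z_uvu, self.z_snp),
            "oro": (self.z_epitip, self.z_uvu),
            "hypo": (self.z_epibot, self.z_epitip),
        }[region]

    def region_slope(self, region: str) -> float:
        return dict(
            zip(("naso", "oro", "hypo"), self.region_area_slopes_mm2_per_mm)
        )[region]

    def max_halfwidth(self, region: str) -> float:
        """Largest constriction half-width over the study protrusions."""
        d0 = float(self.constriction_depth_mm2)
        if d0 <= 0:
            return self.constriction_halfwidth_mm
        extra = self.mincsa_slope_mm2_per_mm - self.region_slope(region)
        depths = [d0 - extra * p for p in self.protrusions_mm]
        dmin = min(d for d in depths if d > 0) if any(d > 0 for d in depths) else d0
        return self.constriction_halfwidth_mm * d0 / dmin

    def constriction_center_range(self, region: str) -> tuple[float, float]:
        a, b = self.region_interval(region)
        margin = self.max_halfwidth(region) + 0.5
        lo, hi = a + margin, b - margin
        if lo >= hi:
            raise ValueError(
                f"constriction (half-width up to {margin - 0.5:.1f} mm) does not fit "
                f"inside the {region} region ({b - a:.1f} mm)"
            )
        return lo, hi


def _floored_normal_mean(mu: float, sd: float, floor: float) -> float:
    """E[max(floor, mu + N(0, sd^2))]."""
    if sd == 0:
        return max(floor, mu)
    d = (mu - floor) / sd
    return mu + sd * norm.pdf(d) - (mu - floor) * norm.cdf(-d)


def calibrate_baseline(
    target_mincsa: float = 236.4,
    target_volume_mm3: float = 24000.0,
    level_sd: float = _TOTAL_SD_DEFAULT,
    floor: float = 10.0,
    halfwidth: float = 6.0,
    total_length: float = 80.5,
) -> tuple[float, float]:
    """Solve (base area, constriction depth) for the P0 calibration targets.

    The P0 minCSA is max(floor, base - depth + level noise); its floored
    mean is matched to ``target_mincsa`` (the floor makes the naive
    unfloored calibration biased high). The unfloored P0 volume is
    base * total_length - depth * halfwidth (the cos^2 dip integrates to
    depth x half-width), matched to ``target_volume_mm3``.
    """
    mu0 = brentq(
        lambda m: _floored_normal_mean(m, level_sd, floor) - target_mincsa,
        floor - 10 * level_sd - 1.0,
        target_mincsa + 1.0,
        xtol=1e-10,
    )
    base = (target_volume_mm3 - mu0 * halfwidth) / (total_length - halfwidth)
    depth = base - mu0
    if depth < 0:
        raise ValueError("calibration yields a negative constriction depth")
    return float(base), float(depth)


@dataclass
class ScanParams:
    residual_mm2: float
    tilt_deg: tuple[float, float, float]
    retained: bool
    noise_seed: int


@dataclass
class PatientParams:
    """Per-patient random effects, covariates, and per-scan draws."""

    patient_id: str
    index: int
    level_offset_mm2: float
    constriction_region: str
    constriction_center_mm: float
    reconstruction: str
    radiotherapy: bool
    stopbang: int
    scans: dict[float, ScanParams] = field(default_factory=dict)

    @property
    def covariates(self) -> dict:
        return {
            "reconstruction": self.reconstruction,
            "radiotherapy": self.radiotherapy,
            "stopbang": self.stopbang,
        }


def sample_cohort(spec: PhantomSpec, n_patients: int, seed: int) -> list[PatientParams]:
    """Draw a reproducible cohort of patients with per-scan parameters.

    Per-patient randomness comes from ``SeedSequence(seed, spawn_key=(i,))``
    so growing the cohort never reshuffles existing patients. Scans are
    retained independently with the per-protrusion probabilities in
    ``spec.missingness`` (missing completely at random).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    patients = []
    for i in range(n_patients):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        offset = float(rng.normal(0.0, spec.patient_sd_mm2))
        region = "naso" if rng.random() < spec.naso_constriction_prob else "oro"
        lo, hi = spec.constriction_center_range(region)
        center = float(rng.uniform(lo, hi))
        reconstruction = (
            "radial_forearm" if rng.random() < spec.p_radial_forearm else "other"
        )
        radiotherapy = bool(rng.random() < spec.p_radiotherapy)
        cat = rng.choice(3, p=np.asarray(spec.stopbang_probs) / sum(spec.stopbang_probs))
        stopbang = int(rng.integers(*((0, 3), (3, 5), (5, 9))[cat]))
        scans = {}
        for j, p in enumerate(spec.protrusions_mm):
            residual = float(rng.normal(0.0, spec.residual_sd_mm2))
            tilt = tuple(float(t) for t in rng.uniform(-spec.tilt_max_deg, spec.tilt_max_deg, 3))
            retained = bool(rng.random() < spec.missingness[min(j, len(spec.missingness) - 1)])
            noise_seed = int(
                np.random.SeedSequence(entropy=seed, spawn_key=(i, j, 7)).generate_state(1)[0]
            )
            scans[float(p)] = ScanParams(residual, tilt, retained, noise_seed)
        patients.append(
            PatientParams(
                patient_id=f"P{i + 1:03d}",
                index=i,
                level_offset_mm2=offset,
                constriction_region=region,
                constriction_center_mm=center,
                reconstruction=reconstruction,
                radiotherapy=radiotherapy,
                stopbang=stopbang,
                scans=scans,
            )
        )
    return patients


@dataclass
class GroundTruth:
    """Closed-form truth for one scan: profile parameters and metrics."""

    protrusion_mm: float
    region_levels_mm2: dict[str, float]
    dip_region: str
    dip_center_mm: float
    dip_depth_mm2: float
    dip_halfwidth_mm: float
    floor_mm2: float
    z_intervals: dict[str, tuple[float, float]]
    mincsa_mm2: float = 0.0
    mincsa_z_mm: float = 0.0
    mincsa_region: str = ""
    meancsa_mm2: dict[str, float] = field(default_factory=dict)
    meancsa_overall_mm2: float = 0.0
    volume_cm3: dict[str, float] = field(default_factory=dict)
    volume_total_cm3: float = 0.0

    @property
    def total_length_mm(self) -> float:
        return self.z_intervals["naso"][1] - self.z_intervals["hypo"][0]

    def area(self, z: np.ndarray) -> np.ndarray:
        """Continuous area profile A(z), zero outside the airway extent."""
        z = np.asarray(z, dtype=float)
        lo = self.z_intervals["hypo"][0]
        hi = self.z_intervals["naso"][1]
        level = np.zeros_like(z)
        inside = (z >= lo) & (z <= hi)
        for region, (a, b) in self.z_intervals.items():
            sel = (z > a) & (z <= b) if region != "hypo" else (z >= a) & (z <= b)
            level[sel] = self.region_levels_mm2[region]
        if self.dip_depth_mm2 > 0:
            u = z - self.dip_center_mm
            w = self.dip_halfwidth_mm
            in_dip = np.abs(u) <= w
            level = level - np.where(
                in_dip, self.dip_depth_mm2 * np.cos(np.pi * u / (2 * w)) ** 2, 0.0
            )
        return np.where(inside, np.maximum(level, self.floor_mm2), 0.0)

    def radius(self, z: np.ndarray) -> np.ndarray:
        return np.sqrt(self.area(z) / np.pi)

    def area_extended(self, z: np.ndarray, extension_mm: float) -> np.ndarray:
        """Profile with the end cross-sections continued ``extension_mm``
        beyond the landmark levels (nasal cavity above SNP, larynx below
        EpiBot), so measured boundary slices see a full cross-section
        rather than a cap artifact. Metrics are still taken on [EpiBot,
        SNP] only."""
        z = np.asarray(z, dtype=float)
        lo = self.z_intervals["hypo"][0]
        hi = self.z_intervals["naso"][1]
        inside = (z >= lo - extension_mm) & (z <= hi + extension_mm)
        clamped = np.clip(z, lo, hi)
        return np.where(inside, self.area(clamped), 0.0)

    def as_row(self) -> dict:
        return {
            "minCSA_mm2": self.mincsa_mm2,
            "minCSA_region": self.mincsa_region,
            "minCSA_z_mm": self.mincsa_z_mm,
            "meanCSA_naso_mm2": self.meancsa_mm2["naso"],
            "meanCSA_oro_mm2": self.meancsa_mm2["oro"],
            "meanCSA_hypo_mm2": self.meancsa_mm2["hypo"],
            "meanCSA_overall_mm2": self.meancsa_overall_mm2,
            "volume_naso_cm3": self.volume_cm3["naso"],
            "volume_oro_cm3": self.volume_cm3["oro"],
            "volume_hypo_cm3": self.volume_cm3["hypo"],
            "volume_total_cm3": self.volume_total_cm3,
        }


def _dip_region_integral(level: float, depth: float, halfwidth: float,
                         length: float, floor: float) -> float:
    """Exact integral of max(floor, level - depth*cos^2(pi u / 2w)) over the
    host region (the dip's support lies fully inside the region)."""
    if level <= floor:
        return floor * length
    if depth <= 0 or level - depth >= floor:
        return level * length - depth * halfwidth
    # partial flooring under the dip
    q = (level - floor) / depth
    u0 = (2.0 * halfwidth / math.pi) * math.acos(math.sqrt(q))
    cos2_int = u0 + (halfwidth / math.pi) * math.sin(math.pi * u0 / halfwidth)
    correction = 2.0 * u0 * (floor - level) + depth * cos2_int
    return level * length - depth * halfwidth + correction


def analytic_truth(spec: PhantomSpec, params: PatientParams, protrusion_mm: float) -> GroundTruth:
    """Closed-form ground truth for one scan (continuous integrals, no voxels)."""
    if protrusion_mm < 0:
        raise ValueError("protrusion must be non-negative")
    p = float(protrusion_mm)
    scan = params.scans.get(p)
    residual = scan.residual_mm2 if scan is not None else 0.0
    level0 = float(spec.base_area_mm2) + params.level_offset_mm2 + residual
    levels = {r: level0 + spec.region_slope(r) * p for r in ("naso", "oro", "hypo")}

    r0 = params.constriction_region
    d0 = float(spec.constriction_depth_mm2)
    depth = d0 - (spec.mincsa_slope_mm2_per_mm - spec.region_slope(r0)) * p
    if depth <= 0 or d0 <= 0:
        depth, halfwidth = 0.0, spec.constriction_halfwidth_mm
    else:
        halfwidth = spec.constriction_halfwidth_mm * d0 / depth

    floor = spec.area_floor_mm2
    intervals = {r: spec.region_interval(r) for r in ("naso", "oro", "hypo")}
    truth = GroundTruth(
        protrusion_mm=p,
        region_levels_mm2=levels,
        dip_region=r0,
        dip_center_mm=params.constriction_center_mm,
        dip_depth_mm2=depth,
        dip_halfwidth_mm=halfwidth,
        floor_mm2=floor,
        z_intervals=intervals,
    )

    volumes = {}
    for r, (a, b) in intervals.items():
        length = b - a
        if r == r0:
            volumes[r] = _dip_region_integral(levels[r], depth, halfwidth, length, floor)
        else:
            volumes[r] = max(levels[r], floor) * length
    truth.meancsa_mm2 = {r: volumes[r] / (intervals[r][1] - intervals[r][0]) for r in volumes}
    truth.volume_cm3 = {r: v / 1000.0 for r, v in volumes.items()}
    truth.volume_total_cm3 = sum(truth.volume_cm3.values())
    truth.meancsa_overall_mm2 = sum(volumes.values()) / spec.total_length_mm

    # minCSA over naso+oro: candidates are the two flat levels and the dip bottom
    candidates = {"naso": levels["naso"], "oro": levels["oro"]}
    dip_bottom = levels[r0] - depth
    best_region = min(candidates, key=lambda r: (candidates[r], r != "naso"))
    if r0 in candidates and dip_bottom < candidates[best_region]:
        truth.mincsa_region = r0
        truth.mincsa_z_mm = params.constriction_center_mm
        truth.mincsa_mm2 = max(floor, dip_bottom)
    else:
        truth.mincsa_region = best_region
        a, b = intervals[best_region]
        truth.mincsa_z_mm = 0.5 * (a + b)
        truth.mincsa_mm2 = max(floor, candidates[best_region])
    return truth


def _tilt_rotation(tilt_deg: tuple[float, float, float]) -> np.ndarray:
    ax, ay, az = np.radians(tilt_deg)
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


# canonical (pre-tilt) cranial landmark offsets, mm: the four Frankfurt
# fiducials sit coplanar on a constant-z plane 15 mm above SNP
_FH_OFFSETS = {
    "LOr": (-28.0, 32.0),
    "ROr": (28.0, 32.0),
    "LPAE": (-45.0, -35.0),
    "RPAE": (45.0, -35.0),
}
_FH_PLANE_ABOVE_SNP_MM = 15.0


def voxelize_phantom(
    spec: PhantomSpec,
    truth: GroundTruth,
    params: PatientParams,
    margin_mm: float = 6.0,
    tube_extension_mm: float = 8.0,
) -> tuple[VolumeImage, LandmarkSet]:
    """Render one scan: a tilted CT-like volume plus its eight landmarks.

    The whole geometry (airway and all landmarks) is rotated by the scan's
    random head tilt about the airway midpoint so the alignment stage is
    genuinely exercised; airway voxels take ``airway_hu``, surroundings
    ``tissue_hu``, with additive Gaussian noise.
    """
    scan = params.scans.get(truth.protrusion_mm)
    tilt = scan.tilt_deg if scan is not None else (0.0, 0.0, 0.0)
    noise_seed = scan.noise_seed if scan is not None else 0
    rot = _tilt_rotation(tilt)
    total = truth.total_length_mm
    ctr = np.array([0.0, 0.0, total / 2.0])

    lms = {
        "SNP": np.array([0.0, 0.0, total]),
        "UVU": np.array([0.0, 0.0, truth.z_intervals["oro"][1]]),
        "EpiTip": np.array([0.0, 0.0, truth.z_intervals["hypo"][1]]),
        "EpiBot": np.array([0.0, 0.0, 0.0]),
    }
    z_fh = total + _FH_PLANE_ABOVE_SNP_MM
    for label, (ox, oy) in _FH_OFFSETS.items():
        lms[label] = np.array([ox, oy, z_fh])
    landmarks = LandmarkSet({k: rot @ (v - ctr) + ctr for k, v in lms.items()})

    zs = np.linspace(-tube_extension_mm, total + tube_extension_mm, int(total) * 2 + 33)
    r_max = float(truth.radius(np.clip(zs, 0.0, total)).max())
    axis_pts = (rot @ (np.column_stack([np.zeros_like(zs), np.zeros_like(zs), zs]) - ctr).T).T + ctr
    lo = axis_pts.min(axis=0) - r_max - margin_mm
    hi = axis_pts.max(axis=0) + r_max + margin_mm

    spacing = np.asarray(spec.spacing_mm, dtype=float)
    if spec.grid_shape is not None:
        shape = np.asarray(spec.grid_shape, dtype=int)
        origin = ctr - spacing * (shape - 1) / 2.0
        if np.any(lo < origin - spacing / 2) or np.any(hi > origin + spacing * (shape - 1) + spacing / 2):
            raise ValueError("airway (plus margin) exceeds the requested grid bounds")
    else:
        origin = lo
        shape = np.ceil((hi - lo) / spacing).astype(int) + 1

    xs = (origin[0] + spacing[0] * np.arange(shape[0]))[:, None, None]
    ys = (origin[1] + spacing[1] * np.arange(shape[1]))[None, :, None]
    zg = (origin[2] + spacing[2] * np.arange(shape[2]))[None, None, :]
    rt = rot.T
    dx, dy, dz = xs - ctr[0], ys - ctr[1], zg - ctr[2]
    ux = rt[0, 0] * dx + rt[0, 1] * dy + rt[0, 2] * dz + ctr[0]
    uy = rt[1, 0] * dx + rt[1, 1] * dy + rt[1, 2] * dz + ctr[1]
    uz = rt[2, 0] * dx + rt[2, 1] * dy + rt[2, 2] * dz + ctr[2]
    r2 = truth.area_extended(uz, tube_extension_mm) / np.pi
    airway = (ux * ux + uy * uy) <= r2  # zero area outside the extended extent

    hu = np.full(airway.shape, spec.tissue_hu, dtype=np.float32)
    hu[airway] = spec.airway_hu
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(noise_seed)
        hu += rng.normal(0.0, spec.noise_sd_hu, size=hu.shape).astype(np.float32)
    return VolumeImage(hu, spacing, origin, np.eye(3)), landmarks


def truth_table(
    spec: PhantomSpec,
    patients: list[PatientParams],
    only_retained: bool = True,
) -> pd.DataFrame:
    """Long-format cohort table of ground-truth metrics (one row per scan)."""
    rows = []
    for params in patients:
        for p, scan in params.scans.items():
            if only_retained and not scan.retained:
                continue
            truth = analytic_truth(spec, params, p)
            row = {"patient_id": params.patient_id, "protrusion_mm": p}
            row.update(truth.as_row())
            row.update(params.covariates)
            rows.append(row)
    return validate_cohort_table(pd.DataFrame(rows))
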