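"""Competitive seeded region growing for the pharyngeal airway.

The grower assigns every voxel (inside an optional ROI box) to the seed
class reachable at minimal path cost, where a path's cost is the maximum
affinity ``|HU(voxel) - mean seed HU of the class|`` along it (minimax
affinity over 6-connectivity). Ties go to the airway class. The class
affinity uses the seed-mean HU computed once, which keeps the labelling
fully deterministic; on a clean two-intensity image the result reduces to
midpoint thresholding.

A plain HU-threshold mode plus connected-component cleanup is provided as
an independent cross-check.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology

from .io import LandmarkSet, VolumeImage

__all__ = [
    "SeedSet",
    "CleanupReport",
    "grow_from_seeds",
    "threshold_segment",
    "auto_seed",
    "cleanup_mask",
    "segment_airway",
]

log = logging.getLogger(__name__)


@dataclass
class SeedSet:
    """Airway / background seed voxels plus an optional world-mm ROI box."""

    airway: list[tuple[int, int, int]]
    background: list[tuple[int, int, int]]
    roi_world: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.airway = [tuple(int(x) for x in s) for s in self.airway]
        self.background = [tuple(int(x) for x in s) for s in self.background]
        if set(self.airway) & set(self.background):
            raise ValueError("airway and background seeds overlap")

    def validate(self, shape: tuple[int, int, int]) -> None:
        if not self.airway:
            raise ValueError("the airway seed class is empty")
        for s in self.airway + self.background:
            if any(c < 0 or c >= n for c, n in zip(s, shape)):
                raise ValueError(f"seed {s} outside the grid {shape}")

    def roi_slices(self, volume: VolumeImage) -> tuple[slice, slice, slice]:
        if self.roi_world is None:
            return tuple(slice(0, n) for n in volume.data.shape)  # type: ignore[return-value]
        lo_w, hi_w = self.roi_world
        lo = np.floor(volume.world_to_index(np.minimum(lo_w, hi_w))).astype(int)
        hi = np.ceil(volume.world_to_index(np.maximum(lo_w, hi_w))).astype(int) + 1
        lo = np.clip(lo, 0, np.asarray(volume.data.shape))
        hi = np.clip(hi, 0, np.asarray(volume.data.shape))
        if np.any(hi <= lo):
            raise ValueError("ROI box does not intersect the volume")
        return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))  # type: ignore[return-value]


def _minimax_cost(hu: np.ndarray, affinity: np.ndarray, sources: list[int]) -> np.ndarray:
    """Minimax path cost from any source to every voxel (6-connectivity).

    ``affinity`` is the per-voxel cost (|HU - class mean|), flattened;
    a path's cost is the max affinity over its voxels, endpoints included.
    """
    nx, ny, nz = hu.shape
    flat_aff = affinity.ravel()
    dist = np.full(flat_aff.shape, np.inf)
    heap: list[tuple[float, int]] = []
    for s in sources:
        c = flat_aff[s]
        if c < dist[s]:
            dist[s] = c
            heapq.heappush(heap, (c, s))
    sy = nz
    sx = ny * nz
    n_total = nx * ny * nz
    push = heapq.heappush
    pop = heapq.heappop
    while heap:
        d, v = pop(heap)
        if d > dist[v]:
            continue
        k = v % nz
        j = (v // nz) % ny
        i = v // sx
        if i > 0:
            w = v - sx
            nd = d if d > flat_aff[w] else flat_aff[w]
            if nd < dist[w]:
                dist[w] = nd
                push(heap, (nd, w))
        if i < nx - 1:
            w = v + sx
            nd = d if d > flat_aff[w] else flat_aff[w]
            if nd < dist[w]:
                dist[w] = nd
                push(heap, (nd, w))
        if j > 0:
            w = v - sy
            nd = d if d > flat_aff[w] else flat_aff[w]
            if nd < dist[w]:
                dist[w] = nd
                push(heap, (nd, w))
        if j < ny - 1:
            w = v + sy
            nd = d if d > flat_aff[w] else flat_aff[w]
            if nd < dist[w]:
                dist[w] = nd
                push(heap, (nd, w))
        if k > 0:
            w = v - 1
            nd = d if d > flat_aff[w] else flat_aff[w]
            if nd < dist[w]:
                dist[w] = nd
                push(heap, (nd, w))
        if k < nz - 1:
            w = v + 1
            nd = d if d > flat_aff[w] else flat_aff[w]
            if nd < dist[w]:
                dist[w] = nd
                push(heap, (nd, w))
    assert n_total == dist.size
    return dist.reshape(hu.shape)


def grow_from_seeds(volume: VolumeImage, seeds: SeedSet) -> VolumeImage:
    """Label the airway by competitive minimax affinity growth.

    Voxels outside the ROI box (when one is set) are background. Seed
    voxels keep their own class. Returns a uint8 mask on the source grid.
    """
    seeds.validate(volume.data.shape)
    sl = seeds.roi_slices(volume)
    hu = np.asarray(volume.data[sl], dtype=float)
    off = np.array([s.start for s in sl])

    def _local(vox_list):
        out = []
        for s in vox_list:
            loc = np.asarray(s) - off
            if np.all(loc >= 0) and np.all(loc < hu.shape):
                out.append(int(np.ravel_multi_index(tuple(loc), hu.shape)))
        return out

    air_src = _local(seeds.airway)
    bg_src = _local(seeds.background)
    if not air_src:
        raise ValueError("no airway seed inside the ROI")
    if not bg_src:
        # uncontested growth: the whole ROI belongs to the airway class
        local = np.ones(hu.shape, dtype=bool)
    else:
        air_mean = float(np.mean([hu.ravel()[s] for s in air_src]))
        bg_mean = float(np.mean([hu.ravel()[s] for s in bg_src]))
        cost_air = _minimax_cost(hu, np.abs(hu - air_mean), air_src)
        cost_bg = _minimax_cost(hu, np.abs(hu - bg_mean), bg_src)
        local = cost_air <= cost_bg  # airway wins ties
    flat = local.ravel()
    flat[air_src] = True
    flat[bg_src] = False
    mask = np.zeros(volume.data.shape, dtype=np.uint8)
    mask[sl] = local.astype(np.uint8)
    return volume.like(mask)


def threshold_segment(volume: VolumeImage, seeds: SeedSet, hu: float = -400.0) -> VolumeImage:
    """Plain HU-threshold segmentation inside the ROI (cross-check mode)."""
    seeds.validate(volume.data.shape)
    sl = seeds.roi_slices(volume)
    mask = np.zeros(volume.data.shape, dtype=np.uint8)
    mask[sl] = (np.asarray(volume.data[sl]) < hu).astype(np.uint8)
    return volume.like(mask)


def auto_seed(
    volume: VolumeImage,
    landmarks: LandmarkSet,
    hu_air: float = -500.0,
    hu_tissue: float = -200.0,
    margin_xy_mm: float = 30.0,
    margin_z_mm: float = 5.0,
    step_mm: float = 2.0,
) -> SeedSet:
    """Automatic seeding of an aligned scan, standing in for manual seeds.

    Airway seeds are sub-threshold (< ``hu_air``) voxels sampled along the
    SNP-UVU-EpiTip-EpiBot polyline; background seeds are supra-threshold
    voxels on the boundary of the ROI box (the landmark extent plus a
    margin).
    """
    if not volume.is_canonical():
        raise ValueError("auto_seed expects an aligned (canonical) volume")
    chain = landmarks.array(["SNP", "UVU", "EpiTip", "EpiBot"])
    pts = []
    for a, b in zip(chain[:-1], chain[1:]):
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / step_mm)) + 1)
        pts.append(np.linspace(a, b, n))
    pts = np.vstack(pts)

    lo_w = pts.min(axis=0) - np.array([margin_xy_mm, margin_xy_mm, margin_z_mm])
    hi_w = pts.max(axis=0) + np.array([margin_xy_mm, margin_xy_mm, margin_z_mm])

    shape = np.asarray(volume.data.shape)
    idx = np.round(volume.world_to_index(pts)).astype(int)
    keep = np.all((idx >= 0) & (idx < shape), axis=1)
    idx = idx[keep]
    airway = []
    seen = set()
    for ijk in idx:
        t = tuple(int(x) for x in ijk)
        if t in seen:
            continue
        seen.add(t)
        if volume.data[t] < hu_air:
            airway.append(t)
    if not airway:
        raise ValueError("no airway candidate below the HU threshold between the landmark levels")

    lo = np.clip(np.floor(volume.world_to_index(lo_w)).astype(int), 0, shape - 1)
    hi = np.clip(np.ceil(volume.world_to_index(hi_w)).astype(int), 0, shape - 1)
    mid = (lo + hi) // 2
    candidates = []
    for i in (lo[0], hi[0], mid[0]):
        for j in (lo[1], hi[1], mid[1]):
            for k in (lo[2], hi[2], mid[2]):
                if (i, j, k) != tuple(mid):
                    candidates.append((int(i), int(j), int(k)))
    background = [c for c in dict.fromkeys(candidates) if volume.data[c] > hu_tissue]
    if not background:
        raise ValueError("no background candidate above the HU threshold on the ROI shell")
    return SeedSet(airway, background, roi_world=(lo_w, hi_w))


@dataclass
class CleanupReport:
    voxels_removed: int = 0
    voxels_added: int = 0
    components_removed: int = 0
    warning: str | None = None
    changed_fraction: float = 0.0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def cleanup_mask(
    mask: VolumeImage,
    seeds: SeedSet | None = None,
    closing_radius: int = 1,
    warn_fraction: float = 0.2,
) -> tuple[VolumeImage, CleanupReport]:
    """Morphological cleanup: optional closing, then keep seeded components.

    Connected components (26-connectivity) not touching any airway seed are
    dropped. Removing more than ``warn_fraction`` of the voxels raises a QC
    warning in the report, never an error.
    """
    data = np.asarray(mask.data).astype(bool)
    before = int(data.sum())
    report = CleanupReport()
    out = data
    if closing_radius > 0:
        out = morphology.closing(out, footprint=morphology.ball(closing_radius))
        report.voxels_added = int(np.sum(out & ~data))
    if seeds is not None and seeds.airway:
        labels = measure.label(out, connectivity=3)
        keep = {labels[s] for s in seeds.airway if labels[s] != 0}
        if keep:
            kept = np.isin(labels, sorted(keep))
            report.components_removed = int(labels.max() - len(keep))
            out = kept
    report.voxels_removed = int(np.sum(data & ~out))
    if before > 0:
        report.changed_fraction = (report.voxels_removed + report.voxels_added) / before
        if report.voxels_removed / before > warn_fraction:
            report.warning = (
                f"cleanup removed {report.voxels_removed}/{before} voxels "
                f"(> {warn_fraction:.0%})"
            )
            log.warning(report.warning)
    return mask.like(out.astype(np.uint8)), report


def segment_airway(
    volume: VolumeImage,
    landmarks: LandmarkSet,
    method: str = "grow",
    hu: float = -400.0,
    closing_radius: int = 1,
    seeds: SeedSet | None = None,
) -> tuple[VolumeImage, SeedSet, CleanupReport]:
    """Seed (automatically unless given), grow or threshold, and clean up."""
    if seeds is None:
        seeds = auto_seed(volume, landmarks)
    if method == "grow":
        raw = grow_from_seeds(volume, seeds)
    elif method == "threshold":
        raw = threshold_segment(volume, seeds, hu=hu)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    clean, report = cleanup_mask(raw, seeds=seeds, closing_radius=closing_radius)
    return clean, seeds, report
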