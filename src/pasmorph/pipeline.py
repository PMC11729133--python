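"""End-to-end orchestration: simulate -> align -> segment -> metrics -> stats.

Every stage is importable on its own; this module wires them together
with per-scan QC, per-scan failure isolation, and a deterministic
seeding scheme (sub-seeds are derived from the master seed by patient
and scan counters, so growing the cohort never reshuffles existing
patients).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom
from .alignment import align_scan
from .io import LandmarkSet, VolumeImage, validate_cohort_table, write_landmarks, write_volume
from .metrics import AirwayMetrics, compute_metrics, csa_profile, region_bounds
from .segmentation import segment_airway
from .stats import cohort_report

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "measure_scan", "spec_for"]

log = logging.getLogger(__name__)

RESOLUTIONS = {
    "paper": (0.76, 0.76, 0.9),
    "coarse": (1.52, 1.52, 1.8),
}


@dataclass
class RunConfig:
    """Configuration of a full simulated-cohort run."""

    n_patients: int = 50
    seed: int = 1
    resolution: str = "paper"  # 'paper' (0.76/0.76/0.9 mm) or 'coarse' (doubled)
    method: str = "grow"  # 'grow' or 'threshold'
    hu_threshold: float = -400.0
    closing_radius: int = 1
    noise_sd_hu: float = 20.0
    out_dir: str | None = None
    write_volumes: bool = False
    qc_plane_residual_mm: float = 2.0
    qc_zero_slice_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.resolution not in RESOLUTIONS:
            raise ValueError(f"unknown resolution preset {self.resolution!r}")
        if self.method not in ("grow", "threshold"):
            raise ValueError(f"unknown segmentation method {self.method!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def spec_for(config: RunConfig) -> phantom.PhantomSpec:
    return phantom.PhantomSpec(
        spacing_mm=RESOLUTIONS[config.resolution],
        noise_sd_hu=config.noise_sd_hu,
    )


def measure_scan(
    volume: VolumeImage,
    landmarks: LandmarkSet,
    method: str = "grow",
    hu_threshold: float = -400.0,
    closing_radius: int = 1,
    fill_hu: float = 40.0,
) -> tuple[AirwayMetrics, dict]:
    """The full measurement chain for one scan.

    Aligns to the Frankfurt plane, auto-seeds, segments, partitions by
    landmark levels and computes the metrics. Returns the metrics plus a
    QC dict (plane residual, rotation angle, mask voxel count, zero-area
    slices, cleanup report).
    """
    aligned, moved, _, qc = align_scan(volume, landmarks, fill=fill_hu)
    mask, _seeds, cleanup = segment_airway(
        aligned, moved, method=method, hu=hu_threshold, closing_radius=closing_radius
    )
    bounds = region_bounds(moved)
    profile = csa_profile(mask, bounds)
    result = compute_metrics(profile, bounds)
    qc.update(
        mask_voxels=int(np.asarray(mask.data, dtype=bool).sum()),
        zero_area_slices=int((profile["area_mm2"] == 0).sum()),
        n_slices=int(len(profile)),
        cleanup=cleanup.as_dict(),
        flags=list(result.flags),
    )
    return result, qc


@dataclass
class PipelineResult:
    table: pd.DataFrame
    truth: pd.DataFrame
    report: dict
    qc: list[dict] = field(default_factory=list)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Simulate a cohort, measure every retained scan, and fit the stats.

    A failing scan is logged and skipped (the cohort survives partial
    failures); if every scan fails the run errors out. Deterministic for
    a fixed config.
    """
    spec = spec_for(config)
    patients = phantom.sample_cohort(spec, config.n_patients, config.seed)
    truth_df = phantom.truth_table(spec, patients)

    rows: list[dict] = []
    qc_records: list[dict] = []
    out_dir = Path(config.out_dir) if config.out_dir else None
    for params in patients:
        for p, scan in sorted(params.scans.items()):
            if not scan.retained:
                continue
            try:
                truth = phantom.analytic_truth(spec, params, p)
                volume, landmarks = phantom.voxelize_phantom(spec, truth, params)
                if out_dir is not None and config.write_volumes:
                    stem = f"{params.patient_id}_P{int(p)}"
                    write_volume(volume, out_dir / "volumes" / f"{stem}.nrrd")
                    write_landmarks(landmarks, out_dir / "landmarks" / f"{stem}.json")
                result, qc = measure_scan(
                    volume,
                    landmarks,
                    method=config.method,
                    hu_threshold=config.hu_threshold,
                    closing_radius=config.closing_radius,
                    fill_hu=spec.tissue_hu,
                )
            except Exception:  # noqa: BLE001 - per-scan isolation is the contract
                log.exception("scan %s P%g failed; skipping", params.patient_id, p)
                qc_records.append(
                    {"patient_id": params.patient_id, "protrusion_mm": p, "failed": True}
                )
                continue
            qc["patient_id"] = params.patient_id
            qc["protrusion_mm"] = p
            qc["warnings"] = []
            if qc["fh_plane_rms_mm"] > config.qc_plane_residual_mm:
                qc["warnings"].append("plane residual above QC threshold")
            if qc["n_slices"] and qc["zero_area_slices"] / qc["n_slices"] > config.qc_zero_slice_fraction:
                qc["warnings"].append("zero-area slice fraction above QC threshold")
            for w in qc["warnings"]:
                log.warning("%s P%g: %s", params.patient_id, p, w)
            qc_records.append(qc)
            row = {"patient_id": params.patient_id, "protrusion_mm": p}
            row.update(result.as_row())
            row.update(params.covariates)
            rows.append(row)
    if not rows:
        raise RuntimeError("every scan failed; nothing to analyse")
    table = validate_cohort_table(pd.DataFrame(rows))
    report = cohort_report(table)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "metrics.csv", index=False)
        truth_df.to_csv(out_dir / "truth.csv", index=False)
        (out_dir / "stats.json").write_text(json.dumps(report, indent=1, default=float))
        (out_dir / "qc.json").write_text(json.dumps(qc_records, indent=1, default=float))
    return PipelineResult(table=table, truth=truth_df, report=report, qc=qc_records)
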