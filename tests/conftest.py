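import numpy as np
import pytest

from pasmorph import (
    PhantomSpec,
    analytic_truth,
    sample_cohort,
    voxelize_phantom,
)

COARSE = (1.52, 1.52, 1.8)
PAPER = (0.76, 0.76, 0.9)


@pytest.fixture(scope="session")
def coarse_spec() -> PhantomSpec:
    return PhantomSpec(spacing_mm=COARSE)


@pytest.fixture(scope="session")
def paper_spec() -> PhantomSpec:
    return PhantomSpec(spacing_mm=PAPER)


@pytest.fixture(scope="session")
def quiet_spec() -> PhantomSpec:
    """Noise-free, untilted cohort at paper resolution (geometry checks)."""
    return PhantomSpec(
        spacing_mm=PAPER,
        noise_sd_hu=0.0,
        tilt_max_deg=0.0,
        patient_sd_mm2=0.0,
        residual_sd_mm2=0.0,
        missingness=(1.0, 1.0, 1.0),
    )


def cylinder_spec(radius_mm: float = 10.0, spacing: float = 0.5) -> PhantomSpec:
    """A constant-area circular tube: area pi r^2 everywhere, no noise."""
    return PhantomSpec(
        spacing_mm=(spacing, spacing, spacing),
        base_area_mm2=np.pi * radius_mm**2,
        constriction_depth_mm2=0.0,
        region_area_slopes_mm2_per_mm=(0.0, 0.0, 0.0),
        mincsa_slope_mm2_per_mm=0.0,
        patient_sd_mm2=0.0,
        residual_sd_mm2=0.0,
        tilt_max_deg=0.0,
        noise_sd_hu=0.0,
    )


@pytest.fixture(scope="session")
def coarse_scan(coarse_spec):
    """One voxelized coarse phantom (tilted, noisy) with its truth."""
    params = sample_cohort(coarse_spec, 3, seed=11)[1]
    truth = analytic_truth(coarse_spec, params, 0.0)
    volume, landmarks = voxelize_phantom(coarse_spec, truth, params)
    return coarse_spec, params, truth, volume, landmarks
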