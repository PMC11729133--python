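import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pasmorph import (
    LandmarkSet,
    RigidTransform,
    VolumeImage,
    analytic_truth,
    build_fh_transform,
    fit_fh_plane,
    resample_to_fh,
    sample_cohort,
    voxelize_phantom,
)
from pasmorph.alignment import align_scan
from pasmorph.io import REQUIRED_LANDMARKS
from pasmorph.metrics import csa_profile, region_bounds
from pasmorph.segmentation import segment_airway

def _rot(axis, deg):
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _fh_set(z=7.0):
    return LandmarkSet(
        {
            "LOr": [-28.0, 32.0, z],
            "ROr": [28.0, 32.0, z],
            "LPAE": [-45.0, -35.0, z],
            "RPAE": [45.0, -35.0, z],
            "SNP": [0.0, 0.0, z - 15],
            "UVU": [0.0, 0.0, z - 45],
            "EpiTip": [0.0, 0.0, z - 66],
            "EpiBot": [0.0, 0.0, z - 95],
        }
    )


def test_horizontal_coplanar_points_give_unit_z_normal():
    normal, point, rms = fit_fh_plane(_fh_set(z=7.0))
    np.testing.assert_allclose(normal, [0, 0, 1], atol=1e-12)
    assert rms == pytest.approx(0.0, abs=1e-9)
    assert point[2] == pytest.approx(7.0)


def test_rotated_coplanar_points_recover_rotated_normal():
    R = _rot("x", 17.0) @ _rot("y", -9.0)
    lms = _fh_set().transformed(lambda p: R @ p)
    normal, _, rms = fit_fh_plane(lms)
    np.testing.assert_allclose(normal, R @ [0, 0, 1], atol=1e-9)
    assert rms == pytest.approx(0.0, abs=1e-9)


def test_noncoplanar_plane_matches_independent_eigen_oracle():
    """TLS plane = smallest-eigenvector of the centered covariance matrix."""
    rng = np.random.default_rng(4)
    lms = _fh_set()
    for k in ("LOr", "ROr", "LPAE", "RPAE"):
        lms.positions[k] = lms.positions[k] + rng.normal(0, 1.5, 3)
    normal, point, rms = fit_fh_plane(lms)
    pts = lms.array(("LOr", "ROr", "LPAE", "RPAE"))
    centered = pts - pts.mean(axis=0)
    evals, evecs = np.linalg.eigh(centered.T @ centered)
    oracle = evecs[:, 0] * np.sign(evecs[2, 0])
    np.testing.assert_allclose(np.abs(normal @ oracle), 1.0, atol=1e-12)
    # rms equals the root-mean-square point-plane distance
    dists = centered @ normal
    assert rms == pytest.approx(np.sqrt(np.mean(dists**2)), abs=1e-12)


def test_collinear_points_raise():
    lms = _fh_set()
    for i, k in enumerate(("LOr", "ROr", "LPAE", "RPAE")):
        lms.positions[k] = np.array([float(i), 0.0, 0.0])
    with pytest.raises(ValueError, match="collinear"):
        fit_fh_plane(lms)


def test_already_aligned_landmarks_give_identity_rotation():
    t = build_fh_transform(_fh_set())
    np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)


@pytest.mark.parametrize("deg", [10.0, -25.0])
def test_known_tilt_angle_is_recovered(deg):
    lms = _fh_set().transformed(lambda p: _rot("x", deg) @ p)
    t = build_fh_transform(lms)
    assert t.angle_deg == pytest.approx(abs(deg), abs=1e-6)


def test_random_rigid_motion_composes_to_same_aligned_positions():
    """Transforming then aligning matches aligning the originals (1e-6 mm)."""
    rng = np.random.default_rng(7)
    base = _fh_set()
    aligned_ref = base.transformed(build_fh_transform(base).apply)
    for _ in range(5):
        R = (
            _rot("x", rng.uniform(-30, 30))
            @ _rot("y", rng.uniform(-30, 30))
            @ _rot("z", rng.uniform(-180, 180))
        )
        shift = rng.uniform(-80, 80, 3)
        moved = base.transformed(lambda p: R @ p + shift)
        aligned = moved.transformed(build_fh_transform(moved).apply)
        for k in REQUIRED_LANDMARKS:
            np.testing.assert_allclose(aligned[k], aligned_ref[k], atol=1e-6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_alignment_is_rigid_and_levels_fh_landmarks(seed):
    """Pairwise distances preserved within 1e-6 mm; FH landmark z-spread
    bounded by the plane residual after alignment."""
    rng = np.random.default_rng(seed)
    lms = _fh_set()
    for k in ("LOr", "ROr", "LPAE", "RPAE"):
        lms.positions[k] = lms.positions[k] + rng.normal(0, 2.0, 3)
    R = _rot("x", rng.uniform(-20, 20)) @ _rot("z", rng.uniform(-90, 90))
    moved = lms.transformed(lambda p: R @ p + rng.uniform(-50, 50, 3))
    t = build_fh_transform(moved)
    aligned = moved.transformed(t.apply)
    labels = list(REQUIRED_LANDMARKS)
    before = moved.array(labels)
    after = aligned.array(labels)
    d_before = np.linalg.norm(before[:, None] - before[None], axis=-1)
    d_after = np.linalg.norm(after[:, None] - after[None], axis=-1)
    np.testing.assert_allclose(d_after, d_before, atol=1e-6)
    _, _, rms = fit_fh_plane(moved)
    zs = np.array([aligned[k][2] for k in ("LOr", "ROr", "LPAE", "RPAE")])
    # after alignment each FH landmark's z is its signed plane-fit residual:
    # they average zero and none can exceed sqrt(4) * rms
    assert abs(zs.mean()) <= 1e-9
    assert np.abs(zs).max() <= 2 * rms + 1e-6


def test_alignment_is_idempotent():
    rng = np.random.default_rng(3)
    lms = _fh_set()
    for k in ("LOr", "ROr", "LPAE", "RPAE"):
        lms.positions[k] = lms.positions[k] + rng.normal(0, 1.0, 3)
    once = lms.transformed(build_fh_transform(lms).apply)
    twice = once.transformed(build_fh_transform(once).apply)
    for k in REQUIRED_LANDMARKS:
        np.testing.assert_allclose(twice[k], once[k], atol=1e-6)


def test_rigid_transform_contract():
    with pytest.raises(ValueError):
        RigidTransform(np.diag([1.0, 1.0, 2.0]), np.zeros(3))
    with pytest.raises(ValueError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
    t = RigidTransform(_rot("y", 40.0), np.array([3.0, -2.0, 9.0]))
    pts = np.random.default_rng(0).normal(0, 30, (10, 3))
    np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-6)


def test_identity_resample_is_voxel_identical():
    rng = np.random.default_rng(5)
    vol = VolumeImage(rng.normal(0, 100, (12, 10, 8)).astype(np.float32), (1, 1, 1), (0, 0, 0))
    out = resample_to_fh(vol, RigidTransform.identity(), fill=0.0)
    assert out.data.shape == vol.data.shape
    np.testing.assert_allclose(out.data, vol.data, atol=1e-3)


def _dice(a, b):
    a, b = a.astype(bool), b.astype(bool)
    return 2 * np.sum(a & b) / (np.sum(a) + np.sum(b))


def _resample_on(source, target, order=0, cval=0.0):
    """Lookup of a source volume at the target grid's voxel centres."""
    from scipy.ndimage import map_coordinates

    idx = np.indices(target.data.shape).reshape(3, -1).T
    world = target.index_to_world(idx)
    src = source.world_to_index(world).T
    vals = map_coordinates(source.data.astype(np.float32), src, order=order, cval=cval)
    return vals.reshape(target.data.shape)


def test_tilted_then_aligned_mask_overlaps_never_tilted(paper_spec):
    """Rotate the phantom ~10 deg, align, segment: Dice vs the never-tilted
    phantom's mask must reach 0.98."""
    import dataclasses

    params = sample_cohort(paper_spec, 1, seed=5)[0]
    scan0 = params.scans[0.0]
    tilted = dataclasses.replace(scan0, tilt_deg=(7.0, -5.0, 4.0))
    flat = dataclasses.replace(scan0, tilt_deg=(0.0, 0.0, 0.0))
    truth = analytic_truth(paper_spec, params, 0.0)

    params.scans[0.0] = flat
    vol_flat, lms_flat = voxelize_phantom(paper_spec, truth, params)
    params.scans[0.0] = tilted
    vol_tilt, lms_tilt = voxelize_phantom(paper_spec, truth, params)
    params.scans[0.0] = scan0

    al_flat, mlms_flat, _, _ = align_scan(vol_flat, lms_flat, fill=paper_spec.tissue_hu)
    al_tilt, mlms_tilt, _, _ = align_scan(vol_tilt, lms_tilt, fill=paper_spec.tissue_hu)
    mask_flat, _, _ = segment_airway(al_flat, mlms_flat)
    mask_tilt, _, _ = segment_airway(al_tilt, mlms_tilt)
    # fractional-occupancy transfer: the two grids differ by sub-voxel offsets
    common = _resample_on(mask_tilt, mask_flat, order=1) >= 0.5
    assert _dice(np.asarray(mask_flat.data), common) >= 0.98


def test_two_resamples_agree_with_one_composed_resample(quiet_spec):
    params = sample_cohort(quiet_spec, 1, seed=9)[0]
    truth = analytic_truth(quiet_spec, params, 0.0)
    vol, _ = voxelize_phantom(quiet_spec, truth, params)
    t1 = RigidTransform(_rot("x", 6.0), np.zeros(3))
    t2 = RigidTransform(_rot("z", 11.0), np.array([2.0, 0.0, -3.0]))
    once = resample_to_fh(vol, t2.compose(t1), fill=quiet_spec.tissue_hu)
    stepwise = resample_to_fh(
        resample_to_fh(vol, t1, fill=quiet_spec.tissue_hu), t2, fill=quiet_spec.tissue_hu
    )
    common = _resample_on(stepwise, once, order=1, cval=quiet_spec.tissue_hu)
    diff = np.abs(np.asarray(once.data, dtype=float) - common)
    assert np.mean(diff) < 20.0  # below the default HU noise floor
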