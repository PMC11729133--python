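# Methods

This note records the model behind the phantom cohort, the measurement
chain, the statistical machinery, and the numerical choices — including
where the design was genuinely open and what the package chose.

## Coordinate conventions

All world coordinates are RAS millimetres (+x patient-right, +y
anterior, +z superior); axial slices are constant-z planes. Voxel
indexing is 0-based along (x, y, z), a voxel's world position is its
centre, and files in LPS dialects (NRRD via SimpleITK, Slicer-style
markup JSON declaring `"coordinateSystem": "LPS"`) are sign-flipped in
x/y at the I/O boundary. Areas are reported in mm² and volumes in cm³;
internal arithmetic is in mm³.

## The phantom cohort

Each patient's airway is a straight vertical tube with circular
cross-section of area A(z). Only area-based metrics are analysed, so the
cross-sectional *shape* is irrelevant; a circle is the simplest shape
with the right area. The profile is piecewise constant over the three
pharyngeal regions plus one smooth constriction:

    A(z) = max(floor, base + b_i + ε_ij + s_r(z)·p − D(p)·cos²(π(z−c)/2w(p)))

with, per scan, patient level offset `b_i ~ N(0, σ_b²)`, scan residual
`ε_ij ~ N(0, σ_e²)`, protrusion `p` ∈ {0, 4, 8} mm, and region slopes
`s_r` (defaults 21.9 / 25.8 / 13.9 mm²/mm for naso / oro / hypopharynx).
The constriction (depth D, half-width w, centre c) sits in the
nasopharynx with probability 0.92 and otherwise in the oropharynx, so
the minCSA localizes in the nasopharynx at the clinically observed rate.

**Why a cos² bump and not a Gaussian.** The dip has compact support
[c − w, c + w] and an elementary integral (∫dip = D·w), so every truth
metric is closed-form and the dip can be kept strictly inside its host
region. Its centre is drawn uniformly from the sub-interval of the host
region that keeps the support inside at every study protrusion.

**Injecting a separate minCSA slope.** The minCSA slope (24.9 mm²/mm by
default) exceeds the host region's mean-CSA slope, which an additive
region effect alone cannot produce. The depth therefore shrinks with
protrusion at rate `s_min − s_host`, while the width grows to hold the
product D·w — the dip's area integral — constant. Consequently the dip
bottom rises at exactly `s_min` per mm while regional means and volumes
keep exactly their injected slopes. The truth minCSA reduces to
`max(floor, base − D₀ + s_min·p + b_i + ε_ij)` for every patient.

**Region lengths.** The three regional slopes, the overall meanCSA slope
(20.0 mm²/mm) and the total-volume slope (1.61 cm³/mm) are mutually
consistent only if Σ s_r·L_r = 1610 mm³/mm and Σ s_r·L_r / Σ L_r = 20.0,
forcing a total length of 80.5 mm. The defaults L = (30.0, 21.1, 29.4)
mm (naso, oro, hypo) satisfy both to four significant figures and are
anatomically plausible for a supine adult.

**Noise split and calibration.** The between/within split of the area
level noise is not identifiable from published summaries; the default
puts 70% of the variance between patients (σ_b² = 0.7·192.2²,
σ_e² = 0.3·192.2²) and both parameters are plain config fields. The
total SD is calibrated to the P0 minCSA spread (192.2 mm²). One shared
level shift cannot simultaneously match independently published spreads
of other metrics (it implies a P0 total-volume SD of ≈15.5 cm³); minCSA
was chosen because it is the study's primary quantity.

A 10 mm² area floor prevents unphysical non-positive areas. Because the
level noise is large, the floor truncates the lower tail: naively
setting `base − D₀` to the target P0 minCSA mean would bias the floored
mean ≈ +11 mm² high. The defaults therefore solve (by Brent's method at
spec construction) for the value whose *floored* mean equals 236.4 mm²,
and then set the base area so the unfloored P0 volume integral is
24.0 cm³ (flooring adds ≈ +0.5 cm³, ~2%). A residual, unavoidable
consequence of floor-plus-additive-normal noise is a mild attenuation of
fitted slopes (truncation is stronger at P0 than at P8): about
−1.3 mm²/mm on the minCSA slope and −3…−4% on the others. This is a
property of the declared noise model, not of the estimator, and stays
well inside the acceptance tolerances.

**Scan-level structure.** Scans are retained independently with
probability 48/50, 45/50, 37/50 at P0/P4/P8 (missing completely at
random; no mechanism is published). Head tilt is uniform within ±5° per
axis per scan. Covariates (radial-forearm reconstruction 48%,
radiotherapy 26%, STOP-BANG risk mix 74/22/4%) are drawn independently;
they carry no effect on the airway by default, so group contrasts on
phantom cohorts test calibration of the test, not a built-in effect.

**Voxelization.** Airway voxels take −1000 HU, surroundings +40 HU, plus
i.i.d. Gaussian noise (default SD 20 HU). The whole geometry — tube and
all eight landmarks — is rotated by the scan's tilt about the airway
midpoint, so alignment is genuinely exercised. The tube continues 8 mm
beyond the SNP and EpiBot levels (the real airway does not end at the
landmark planes); without this, boundary slices show cap partial-volume
artifacts that corrupt the minCSA. The grid auto-sizes to the rotated
airway plus a 6 mm margin; per-scan noise seeds derive from
`SeedSequence(master, spawn_key=(patient, scan))`, so enlarging a cohort
never reshuffles existing patients.

**What the phantoms do not emulate:** real cranial anatomy (the
Frankfurt landmarks are synthetic fiducials at fixed offsets), soft
tissue heterogeneity and scanner physics (beam hardening, PSF), airway
curvature and non-circular lumina, swallowing/motion artifacts, and any
true covariate effect. Passing tests therefore demonstrate correctness
of the measurement and inference chain under the declared geometry and
noise, not clinical validity on patient CTs.

## Alignment

Four landmarks over-determine the Frankfurt plane, so a total-least-
squares fit (SVD of the centred 4×3 matrix) is used and its rms residual
is reported as QC (phantoms: ≈0; a >2 mm residual flags implausible
landmarks). The rotation maps the fitted normal (oriented superior) to
+z and the LPAE→RPAE axis, projected into the plane, to +x — the yaw
convention makes axial slices consistently oriented; the translation
centres the four-landmark centroid. Volumes are resampled trilinearly
(masks: nearest-neighbour) onto an axis-aligned grid spanning the
transformed bounding box at the input spacing, in a single resampling
from the source grid; out-of-field voxels take a configurable tissue-like
fill.

## Segmentation

"Grow from seeds" is implemented as competitive minimax-affinity growth:
a voxel's cost to a class is the minimum over paths (6-connectivity, to
prevent diagonal leaks through thin walls) of the maximum
|HU − class seed mean| along the path, endpoints included; each voxel
takes the cheaper class, airway winning ties, and seed voxels keep their
class. Class affinities use the seed-mean HU computed once, not
iteratively — determinism is worth more here than adaptivity. On a clean
two-intensity image this reduces to midpoint thresholding (enclosed
islands of the other phase go to the airway by the tie rule). The
implementation is verified voxel-for-voxel against an exhaustive
fixed-point relaxation oracle on ≤10³-voxel instances, and a plain
threshold mode (`method="threshold"`, default −400 HU) provides an
independent route on real runs.

Automatic seeding stands in for the manual clicks of an interactive
session: airway seeds are sub-(−500 HU) voxels sampled every 2 mm along
the SNP–UVU–EpiTip–EpiBot polyline; background seeds are supra-(−200 HU)
voxels on the ROI shell (landmark bounding box + 30 mm laterally, 5 mm
axially). Cleanup keeps 26-connected components touching airway seeds
and optionally applies a morphological closing (default radius 1 voxel);
removing >20% of voxels raises a QC warning, never an error — a large
correction is information, not necessarily a failure.

## Metrics

Cross-sections are measured on axial planes of the aligned volume (not
perpendicular to a centerline): slice area = airway-voxel count × pixel
area. Regions partition the slab by landmark z-levels with half-open,
superior-inclusive intervals (naso (UVU, SNP], oro (EpiTip, UVU], hypo
[EpiBot, EpiTip]) so every slice is counted exactly once. minCSA is the
minimum over naso+oro slices — the hypopharynx is excluded because the
epiglottis is mobile and the laryngeal cartilage collapsible — with ties
broken toward the most superior slice. Region volume is Σ area × slice
spacing; the total is the sum over regions, exactly, by construction.
Slices with zero airway voxels inside the bounds count as area 0 (an
obstructed level is a real level) and raise a QC flag; a region with no
slices is flagged missing rather than reported as zero.

## Statistics

The random-intercept model is fitted by REML with the criterion profiled
down to the variance ratio λ = σ_b²/σ_e²: per patient,
(I + λJ)⁻¹ = I − λ/(1 + λn_i)·J, so the GLS estimate and σ̂_e² are
closed-form in λ and the fit is a 1-D minimization (coarse log-grid with
λ = 0 included, then bounded refinement). Unbalanced cohorts need no row
deletion. Design choices where the original analysis is underspecified:
random intercept only (no random slope); protrusion continuous in mm for
the slope, with the likelihood-ratio test (ML refits, χ²(1)) supplying
the repeated-measures significance; Wald p-values against the normal
reference (no Satterthwaite correction). The fitter agrees with
`statsmodels.MixedLM` to ~1e-7 on the estimates in the cross-check tests
and with a dense-matrix GLS oracle to 1e-8; the LRT's type-I error is
verified at ≈0.05 over 1000 null cohorts. Degenerate inputs: a constant
outcome returns β₁ = 0 with both variances 0; a noise-free linear
outcome returns the exact coefficients; a single protrusion level is a
singular design and errors.

ICC is the two-way mixed-effects, single-measurement, consistency form,
ICC(3,1) = (MS_subjects − MS_error)/(MS_subjects + (k−1)·MS_error),
chosen because one rater re-measures the same scans and a systematic
occasion shift should not count against reliability; >0.8 is labelled
high consistency. Group contrasts use Welch's t (no equal-variance
assumption between reconstruction/radiotherapy groups). The flow-rate
helper returns (A_after/A_before)² — laminar Hagen–Poiseuille resistance
scales with 1/r⁴, so volumetric flow at fixed pressure gradient scales
with area squared. STOP-BANG categories: ≤2 low, 3–4 moderate, ≥5 high.

## Problem sizes and tolerances

Phantom work in the test suite and acceptance script runs at "coarse"
resolution (1.52/1.52/1.8 mm, double the study's 0.76/0.76/0.9 mm
spacing), chosen as the package's standard fast preset; geometry-
sensitive checks (cylinder areas, profile-vs-truth, tilt-align Dice) use
finer grids where the property demands it. Slope-recovery quantities are
reported as means over replicate cohorts (40 in the acceptance script, 5
in the tests) because a single 50-patient cohort estimates a slope with
SE ≈ 2.6–2.9 mm²/mm; averaging isolates the estimator's bias from
cohort sampling noise. Voxelization tolerances: digitized circle areas
are within 2% of πr² at 0.5 mm pixels; measured metrics converge to the
analytic truth as spacing shrinks. Floating-point contracts: rigid
transforms orthonormal within 1e-8 and invertible within 1e-6 mm; I/O
round trips lossless at declared precision.

## Known limitations

* Axial (not centerline-orthogonal) cross-sections; for a near-vertical
  phantom airway the two coincide, for curved real airways they do not.
* The additive-normal level noise with a hard floor mildly attenuates
  fitted slopes (see calibration above) and right-censors nothing — real
  minCSA distributions are right-skewed.
* Covariate effects are not simulated; contrasts on phantoms only check
  test calibration.
* The grower recomputes class affinities once; severely inhomogeneous
  HU distributions would need iterative or edge-based affinities.
* DICOM series import is not implemented (NRRD/MetaImage/NIfTI only).
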