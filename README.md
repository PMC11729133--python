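# pasmorph — posterior airway space morphometry under mandibular protrusion

`pasmorph` quantifies how the posterior airway space (PAS) — the
pharyngeal air column from the posterior nasal spine to the base of the
epiglottis — changes when the mandible is advanced by a known distance,
as with a mandibular advancement device (MAD) in obstructive sleep apnea
(OSA) therapy or in orthognathic surgery planning. It is written for
image-analysis and clinical researchers who want the complete measurement
and inference chain as reproducible, testable code:

1. **Frankfurt-plane alignment** — each CT scan is rigidly rotated so the
   total-least-squares plane through the orbitale and porion landmarks
   (LOr, ROr, LPAE, RPAE) becomes horizontal, with the inter-porion axis
   fixing the yaw.
2. **Airway segmentation** — competitive seeded region growing: every
   voxel joins the seed class (airway vs background) reachable at minimal
   minimax HU-affinity path cost; a plain HU-threshold mode serves as an
   independent cross-check.
3. **Regional metrics** — the segmented airway is partitioned at the
   axial levels of SNP, UVU (uvula tip), EpiTip and EpiBot into
   nasopharynx, oropharynx and hypopharynx; per scan the package reports
   the minimum cross-sectional area (minCSA, over naso+oropharynx only),
   per-region and overall mean CSA (mm²), and per-region and total
   volume (cm³).
4. **Cohort inference** — the protrusion effect is estimated with a
   random-intercept linear mixed model

   y_ij = β₀ + β₁·p_ij + b_i + ε_ij,  b_i ~ N(0, σ_b²), ε_ij ~ N(0, σ_e²),

   where p_ij is the protrusion in mm (0/4/8) of patient i's scan j; the
   model uses every available scan, so missing protrusion levels cost
   information but no rows. β₁ is the per-millimetre effect (e.g. mm² of
   minCSA per mm of advancement). Reliability uses the two-way mixed,
   single-measurement, consistency ICC; planning helpers cover the
   52 mm²/110 mm² minCSA thresholds and the Hagen–Poiseuille flow-rate
   ratio (area ratio squared).

Because no patient data are published for this design, the package ships
a first-class **phantom generator**: CT-like pharynx phantoms (circular
cross-sections with a nasopharyngeal constriction, randomized head tilt,
Gaussian HU noise, per-patient random levels, region-specific per-mm
protrusion effects, and missing-scan patterns) with closed-form ground
truth for every metric, calibrated so a default 50-patient cohort
reproduces the published cohort behaviour (P0 minCSA mean 236.4 mm², P0
volume 24.0 cm³, per-mm slopes 24.9 mm²/mm for minCSA, 21.9/25.8/13.9
mm²/mm for regional meanCSA, 1.61 cm³/mm for volume).

## Worked example

```python
from pasmorph import (PhantomSpec, sample_cohort, analytic_truth,
                      voxelize_phantom, measure_scan, fit_lmm)
from pasmorph.phantom import truth_table

spec = PhantomSpec(spacing_mm=(1.52, 1.52, 1.8))      # half resolution
params = sample_cohort(spec, 3, seed=2)[1]            # one patient
truth = analytic_truth(spec, params, 0.0)             # protrusion 0 mm
volume, landmarks = voxelize_phantom(spec, truth, params)
metrics, qc = measure_scan(volume, landmarks)
print(f"minCSA {metrics.mincsa_mm2:.1f} mm^2 (truth {truth.mincsa_mm2:.1f}), "
      f"volume {metrics.volume_total_cm3:.2f} cm^3 (truth {truth.volume_total_cm3:.2f})")

table = truth_table(PhantomSpec(), sample_cohort(PhantomSpec(), 50, seed=7))
res = fit_lmm(table, "minCSA_mm2")
print(f"minCSA slope {res.beta1:.1f} mm^2 per mm protrusion (SE {res.se_beta1:.1f})")
```

prints

```
minCSA 353.5 mm^2 (truth 345.1), volume 33.81 cm^3 (truth 33.79)
minCSA slope 25.1 mm^2 per mm protrusion (SE 2.9)
```

— the measurement chain recovers this scan's true minCSA to ~2% after
correcting a 3.4° head tilt, and the mixed model recovers the injected
24.9 mm²/mm slope within one standard error on this 50-patient cohort.

## Analysis scripts

The numbered drivers under `analysis/` re-run the study narrative and
write their tables to `results/`:

| script | what it does |
| --- | --- |
| `01_simulate_cohort.py` | simulate 50 patients, write the ground-truth cohort table |
| `02_fit_protrusion_effects.py` | LMM slopes + group contrasts for every metric |
| `03_validate_measurement_chain.py` | voxel pipeline vs analytic truth (bias table) |
| `04_reliability_and_planning.py` | re-measurement ICC, threshold/planning rules, flow ratio |

A `pasmorph` CLI (`simulate / align / segment / metrics / stats /
run-all`) wraps the same library calls for shell use.

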