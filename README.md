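# segstress

Stress-testing radiomic prognostic models against tumor-segmentation
uncertainty.

## The problem

Radiomic features — intensity, shape and texture descriptors computed from a
tumor region on CT — depend on the delineated contour (GTV). Contours are
drawn by hand and vary between observers, yet most biomarker studies extract
features from a *single* contour per patient and report a single model
performance. That number can be deceiving: a model may stratify survival
significantly on the given contours and fall apart under contour variations
well within interobserver range.

`segstress` quantifies this. For researchers building image-biomarker
survival models, it answers three questions:

1. **How sensitive is each feature to plausible re-contouring?**
   Perturbed binary masks are sampled within a hard surface-distance
   tolerance τ of the original (default 1.18 mm, the interobserver scale
   reported for lung GTVs), features are re-extracted per mask, and each
   feature gets an uncertainty-to-effect ratio

   η = median over patients of IQR across mask realizations
   &nbsp;&nbsp;&nbsp;&nbsp;/ IQR across patients of per-patient medians.

   η ≈ 0 means contouring noise is negligible against the between-patient
   signal; η ≈ 1 means the noise swamps it.

2. **How stable is the model?** A Cox proportional-hazards model with
   median risk stratification and a log-rank test is re-run over Monte Carlo
   cohort realizations (one mask realization sampled per patient, with
   replacement, in training and testing sets). The fraction of realizations
   with log-rank p < 0.05 summarises stability; an "ensemble" model (the
   fitted model closest to the coefficient medians) is scored with
   per-patient averaging.

3. **How consistent is each patient's classification?** Every mask
   realization of a patient is classified with the fixed ensemble model;
   agreement is δ = (#majority − #minority) / total ∈ [0, 1].

A synthetic module generates textured ellipsoid phantoms, feature tables
with controllable within-/between-patient spread, and proportional-hazards
survival data, so the whole pipeline is testable without clinical data.

## Worked example

Perturb a radius-10 mm textured ball phantom and look at feature spread:

```python
import numpy as np
from segstress.synthetic import PhantomParams, make_phantom
from segstress.perturb import PerturbationConfig, generate_realizations
from segstress.surface_metrics import surface_distance_summary
from segstress.features import extract_all
from segstress.uncertainty_stats import FeatureRealizations

img, mask = make_phantom(PhantomParams(radius_mm=10.0, seed=0))
cfg = PerturbationConfig(tolerance_mm=1.18, n_realizations=20, seed=0)
realizations = generate_realizations(mask, cfg)

dists = [surface_distance_summary(mask, m, 1.18).max_symmetric_mm for m in realizations]
vols = [m.volume_mm3() for m in realizations]
print(f"max symmetric surface distance: {max(dists):.2f} mm (tolerance 1.18 mm)")
print(f"realized volumes: {min(vols):.0f}-{max(vols):.0f} mm^3 (original {mask.volume_mm3():.0f})")

rows = [extract_all(img, m) for m in [mask] + realizations]
fr = FeatureRealizations(
    patient_ids=["phantom"],
    values={n: np.array([[fv[n] for fv in rows]]) for n in rows[0].keys()},
)
for name in ("glcm_MCC", "glrlm_RunEntropy", "firstorder_Maximum"):
    vals = fr.values[name][0]
    print(f"{name}: original {vals[0]:.4f}, realization IQR "
          f"{np.subtract(*np.percentile(vals, [75, 25])):.4f}")
```

Output:

```
max symmetric surface distance: 1.00 mm (tolerance 1.18 mm)
realized volumes: 4165-4315 mm^3 (original 4224)
glcm_MCC: original 0.8859, realization IQR 0.0053
glrlm_RunEntropy: original 4.6954, realization IQR 0.0225
firstorder_Maximum: original 112.2613, realization IQR 0.0000
```

Every perturbed mask respects the 1.18 mm tolerance while volumes vary by
±2%. Texture features (GLCM maximal correlation coefficient, run entropy)
shift under re-contouring, whereas the first-order Maximum is exactly stable
here — the brightest voxel lies deeper than τ inside the tumor, so no
tolerated contour change can remove it. Collected across a cohort, these
per-patient spreads become the numerator of η.

## Command line

The same steps are exposed as subcommands operating on NIfTI/NRRD volumes
and CSV tables:

```bash
segstress perturb mask.nrrd --tau 1.18 --n 300 --seed 42 --out-dir realizations/
segstress extract --image ct.nii.gz --masks realizations/ --bin-width 25 --out features.csv
segstress eta features.csv --out eta_table.csv
segstress simulate --features-train ftrain.csv --features-test ftest.csv \
    --survival-train strain.csv --survival-test stest.csv \
    --select low4 --n-sim 1000 --seed 42 --out result.json
segstress synth phantom --seed 0 --out-dir fixtures/
```

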