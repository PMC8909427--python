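# Methods

This note documents the models, estimators and numerical choices behind
`segstress`, what the synthetic generators do and do not emulate, and the
package's known limitations.

## Uncertainty-to-effect statistics

**Cohen's d.** For two patient groups A, B the standardized mean difference
is |X̄_A − X̄_B| divided by the pooled SD with (n−1) weighting,
√(((n_A−1)s_A² + (n_B−1)s_B²)/(n_A+n_B−2)). It is symmetric, non-negative
and invariant under common rescaling. A zero pooled variance with unequal
means is an error, not ±∞.

**Total intra-patient variance.** When several protocol factors
(acquisition, segmentation, processing) perturb a feature, their variance
components add together with twice each pairwise covariance:
s²_intrapat = s²_acq + s²_seg + s²_proc + 2COV_acq,seg + 2COV_acq,proc +
2COV_seg,proc. Only the segmentation component is *simulated* by this
package; the composition accepts externally estimated components and
covariances and validates that the total is non-negative.

**η, general form.** η = E[s_intrapat] / IQR(X) compares expected
intra-patient SD against the between-patient interquartile range. The IQR is
a natural effect scale under median stratification: with even groups, the
two group medians sit near the cohort's 0.25 and 0.75 quantiles. Note the
general form divides an SD by an IQR without a 1.349 normal-consistency
factor — it is a ratio of heterogeneous dispersion measures and is used
as written.

**η, segmentation form.** With mask realizations r = 0…R per patient
(realization 0 is the original contour, included in all statistics), the
estimator is internally consistent IQR-over-IQR:

    η = median_i IQR_r(X_ir)  /  IQR_i( median_r(X_ir) ).

For Gaussian additive structure X_ir = μ + b_i + w_ir with b ~ N(0, σ_b²),
w ~ N(0, σ_w²), both IQRs carry the same 1.349 factor, so η → σ_w/σ_b as
patients → ∞ — the parameter-recovery target used in the tests (200
patients × 301 realizations recover σ_w/σ_b = 0.3 within ±0.05). η is
invariant under affine transforms of the feature. A zero denominator (no
between-patient effect) yields a *flagged undefined* estimate — never a
silent 0 or ∞ — and ranking excludes such features with a warning.
Quantiles use linear interpolation (NumPy default, "type 7") throughout;
ranking ties break lexicographically by feature name.

**Agreement δ.** For one patient's realization classifications,
δ = (#majority − #minority)/(#majority + #minority) ∈ [0, 1]; δ = 1 is a
fully consistent patient, δ = 0 an exact tie (only possible for even
realization counts; the default 300 + 1 design cannot tie).

## Mask perturbation within a surface tolerance

**Surface convention.** A mask's surface is the set of foreground voxels
with a 6-connected background (or out-of-grid) neighbour, represented by
their physical centres in mm. All distances are Euclidean in mm, so
anisotropic grids are handled naturally. The surface dice at tolerance τ is
the fraction of both surfaces' points lying within τ of the other surface;
the perturbation contract is the strict reading: max symmetric surface
distance ≤ τ, equivalently surface dice exactly 1 at τ. Voxel-centre
surfaces (rather than mesh surfels) keep this contract exact and cheap to
verify; distances computed by KD-tree queries are exact and are tested
against a brute-force double loop.

**Signed distance.** `signed_distance_field` measures distance to the
nearest *surface voxel centre*, negative inside; surface voxels sit exactly
at 0. The uncertainty ring is {v : |d(v)| ≤ τ} — the only region a tolerated
perturbation may touch.

**Sampler.** One realization is drawn as follows: white noise on the grid
is smoothed with a Gaussian kernel of physical width `smoothness_mm`
(default: τ, so deformation patches have roughly the lateral scale of their
amplitude, as hand-drawn contour differences do); the field is standardized
and scaled to saturate at ±(0.99τ − h) with clipping (h = half the smallest
voxel spacing), giving a symmetric, spatially coherent boundary-displacement
field o(v); the candidate mask is {v : d(v) < o(v) + h}; the largest
26-connected component is kept and internal holes filled; the candidate is
accepted iff the max symmetric surface distance to the original is ≤ τ,
otherwise redrawn (default budget 25 attempts, then a hard error — never a
silent fallback to the original mask). All realizations are treated as
equally probable.

Two numerical choices matter here. The half-voxel shift h accounts for the
geometric boundary lying half a voxel outside the surface voxel centres:
without it, a locally negative offset removes surface voxels (they sit at
d = 0) while additions require offsets near a full voxel, and realized
volumes collapse systematically (≈ −12% on a ball phantom). With it,
single-layer additions and removals are equally likely (measured volume bias
0.4% on the same phantom) and no offset can move the boundary by more than
one voxel layer. Second, the field is normalized by its SD and clipped, not
divided by its global maximum: max-normalization makes typical offsets — and
hence the realized deformation — shrink toward zero as the grid grows.

The acceptance check is still indispensable: on discrete staircase corners
(e.g. single-voxel spikes of an exactly voxel-centred ball), removing one
voxel can open a √2-voxel ≈ 1.41 mm gap > τ, and such candidates are
rejected. Masks dominated by such geometry can exhaust the attempt budget;
the error message points at the τ/smoothness trade-off. Realization i is
generated from an RNG stream derived from (seed, i), so individual
realizations are reproducible regardless of how many are drawn.

## Radiomic features

A documented ~25-feature subset spanning all the texture families used by
the η analysis, under fixed conventions (the common pyradiomics defaults
wherever several IBSI-compliant choices exist):

* **Discretization:** fixed bin size anchored at the ROI minimum,
  level = ⌊(I − min)/W⌋ + 1, default W = 25 HU; applied only inside the mask.
* **First order:** Maximum, Minimum, Mean, Median, population Variance,
  Skewness, Pearson Kurtosis (m₄/m₂², not excess), Energy, binned Entropy
  (log₂), RMS. Constant ROIs define Skewness = Kurtosis = 0.
* **Shape:** volume = voxel count × voxel volume; `SurfaceAreaApprox` counts
  exposed voxel faces; Sphericity = π^⅓(6V)^⅔ / A with A from a
  marching-cubes mesh, because the face-count estimator is biased high by
  ~50% on curved surfaces and would rank a digitized ball below a cube;
  Maximum3DDiameter is the largest pairwise distance between surface voxel
  centres (computed on the convex hull).
* **GLCM:** distance 1, 13 unique 3D directions, symmetric matrices,
  features per direction then averaged: JointEntropy, Contrast, Correlation,
  MCC (√ of the second-largest eigenvalue of Q(i,j) = Σ_k p(i,k)p(j,k)/
  (p_x(i)p_y(k)), restricted to occupied levels).
* **GLRLM:** 13-direction run-length matrices, direction-averaged
  GrayLevelNonUniformity and RunEntropy.
* **GLSZM:** zones are 26-connected same-level components;
  GrayLevelVariance and GrayLevelNonUniformityNormalized.
* **GLDM:** dependence = number of 26-neighbours with identical level
  (α = 0); GrayLevelNonUniformity.
* **NGTDM:** Coarseness = 1/Σ p_i s_i over voxels with at least one in-ROI
  26-neighbour, capped at 10⁶ when the denominator vanishes.

Degenerate single-level ROIs use logged conventions: GLCM Contrast 0,
Correlation and MCC 1, Coarseness capped. Every matrix family is verified
against brute-force enumeration on small random ROIs; an optional
pyradiomics backend hook (`extract_with_backend`) exists for environments
where that package is installed.

## Prognostic stability simulation

The pipeline per realization: (1) log-scale each feature (shifting by
1 − min_train first when the training minimum is ≤ 0), standardize by
training mean/SD, and exclude patients with any |z| > 3 from that
realization's fit or scoring (exclusion, not clipping; test values falling
outside the training log-shift's support are likewise excluded); (2) fit a
Cox proportional-hazards model on the training cohort (partial likelihood
via lifelines, cross-checked against an independent implementation to
1e-4); (3) stratify the test cohort at the median *training* linear
predictor — identical to median hazard-ratio splitting by monotonicity —
and record the two-sample log-rank statistic and p-value.

Monte Carlo stability: each of n_sim iterations samples, independently per
patient, one realization index uniformly with replacement (the same index
for all of a patient's features — one mask, one feature vector) in both
cohorts and re-runs the pipeline. Iteration i uses an RNG stream derived
from (seed, i). Individual iteration failures are recorded; more than 10%
failing aborts the run. `fraction_significant` is the share of successful
iterations with p < 0.05. The default n_sim is 1000 — stability estimates
are well resolved at that scale and grow slowly more precise beyond it.

The ensemble model is the fitted model whose coefficient vector is
least-squares closest to the element-wise coefficient medians (ties: first).
It is then scored on n_sim fresh test realizations; linear predictors are
averaged per patient (averaging on the linear-predictor scale — monotone
relabeling makes the scale choice irrelevant for single realizations but not
for averages) and thresholded at the ensemble model's own training median.
Per-patient δ classifies *all* of a patient's realizations with this fixed
model.

## Synthetic generators: what they emulate, and what not

* `make_phantom` — ellipsoidal tumours with correlated Gaussian texture
  (default: 48³ grid at 1 mm, radius 10 mm, tumour 40 ± 30 HU with 3 mm
  texture correlation, background −800 ± 20 HU). This reproduces the
  *geometry* of the problem (curved boundary, textured interior on a
  distinct background), not the appearance of lung CT: no spiculation,
  vessels, partial-volume rim, or pleural attachment. Feature values on
  phantoms are not clinically meaningful; only their *behaviour under
  perturbation* is.
* `make_feature_table` — Gaussian additive values μ + b_i + w_ir with
  w = 0 at realization 0. Chosen because the η recovery target σ_w/σ_b is
  then analytic. Real radiomic features are skewed and mutually correlated;
  the log-scaling step in the prognostic pipeline exists precisely because
  of that, and the tests exercise it with log-normal inputs.
* `make_survival` — exponential proportional-hazards times (baseline rate
  1/500 per day ≈ 16-month median) with independent exponential censoring
  calibrated to the requested censoring fraction for an average-risk
  patient. Exponential baselines make parameter recovery closed-form; no
  attempt is made to model non-PH effects.
* `make_contrast_cohort` — the paired study design used by the stability
  analysis: four latent prognostic factors b_k ~ N(0,1) per patient drive
  survival (β = 0.2 each); a low-noise feature set observes each b_k with
  σ_w = 0.05 and a high-noise set observes the *same* b_k with σ_w = 0.4
  (designed η ≈ 0.05 vs ≈ 0.4). Any stability difference between the two
  feature sets is therefore attributable to contouring noise alone. β and
  the 30% censoring rate were fixed by a design-phase power calculation so
  that the original-contour test log-rank p lands near 0.01 at n_train =
  200 / n_test = 150 — significant on the given contours yet sensitive to
  uncertainty, which is the regime where stability analysis is informative.

Passing tests on these generators demonstrate the estimators' contracts
(tolerance guarantees, analytic recovery, ordering of stability between
noise levels), not clinical performance on any real cohort.

## Problem sizes and numerical defaults

The test suite and the acceptance script run the full design at reduced
scale: 300 mask realizations per phantom, Gaussian cohorts of 200 patients ×
301 realizations, stability contrasts at n_train = 200, n_test = 150 with
200 pipeline simulations over three cohort seeds. These sizes resolve the
quantities of interest (binomial SE of a stability fraction at n_sim = 200
is ≈ 3.5 points) while keeping a full run in the minutes range on one CPU.

Other numerical choices: significance α = 0.05; masks stored as unsigned
8-bit on disk, boolean in memory; arrays indexed (x, y, z) against the
header affine (SimpleITK's (z, y, x) order is transposed at the I/O
boundary); images resampled with linear interpolation, masks with
nearest-neighbour; resampling preserves physical extent within one voxel.

## Known limitations

* The perturbation sampler is a concrete, testable surrogate for observer
  variability; real re-delineations are not uniform over the tolerance band
  and may be systematically biased (e.g. toward larger volumes).
* Voxel-centre surfaces slightly underestimate distances relative to mesh
  surfels (up to about half a voxel diagonal); τ is interpreted against the
  voxel-centre metric.
* DICOM/RTSTRUCT inputs are out of scope: volumes and masks must arrive as
  NIfTI or NRRD, already co-registered.
* η measures segmentation-induced uncertainty only; acquisition and
  processing components of the variance composition must be estimated
  externally.
* The feature set is a documented subset; full 104-feature parity with
  pyradiomics is reachable only through the optional backend hook.
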