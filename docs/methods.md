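# Methods

## The measurement model

A renal stone on non-contrast CT (CT KUB) is a strongly hyperattenuating
object: several hundred Hounsfield units (HU) against soft tissue and
urine near 0–60 HU. `stonevol` measures stone burden the way
semi-automated clinical volumetry software does:

1. **Threshold.** Every voxel with `HU >= T` is marked as candidate
   stone. The comparison is inclusive so boundary behaviour is exact
   and reproducible. `T` defaults to 130 HU — the conventional
   calcification cut-off — and is an operator-facing parameter, because
   the workflow this emulates is *semi*-automated: the operator picks
   the threshold that separates the stone from its surroundings on the
   case at hand. No morphological opening/closing or hole-filling is
   applied; any such step would change the measured volume.
2. **Label.** Candidate voxels are grouped into individual stones by 3D
   connected components. The default neighbourhood is 26-connected
   (face + edge + corner) so that a stone whose in-plane footprint
   shifts by less than a voxel between slices remains one object;
   6-connectivity is available. Components below `min_voxels`
   (default 2) are discarded as noise speckle. Labels are assigned
   1..n by decreasing voxel count, ties broken by the lexicographically
   smallest `(slice, row, col)` of the component's first voxel, so
   label 1 is always the dominant stone and labelling is deterministic.
   Labelling is fully 3D rather than per-slice-then-stacked; for
   threshold segmentation the two give the same voxel set, and 3D
   labelling keeps multi-slice stones whole.
3. **Measure.** For each stone:
   * voxel-count volume `V = N · s_row · s_col · t` where `N` is the
     voxel count, `s_row, s_col` the in-plane pixel spacing and `t` the
     slice thickness (an exact identity, checked as such);
   * the largest axial slice (most stone pixels; tie → lowest index),
     and on it the major **horizontal** (column-direction) and
     **vertical** (row-direction) axis extents and the cross-sectional
     area;
   * the craniocaudal extent across slices.

   In-plane axes are axis-aligned bounding-box extents, not Feret
   diameters, because the manual protocol they are compared against
   measures maximum diameters *along the image axes*; the two methods
   must share a convention to be correlated meaningfully. Extents
   count whole pixels, `(max idx − min idx + 1) · spacing`: a one-pixel
   stone is one pixel wide, not zero. Whether a clinical package's
   "major vertical axis" is the in-plane row extent or the craniocaudal
   extent is genuinely ambiguous; we compute both and treat the
   in-plane extent as the vertical axis, reporting the craniocaudal
   extent separately.

## Manual ellipsoid estimators

From three measured diameters, ordered `a >= c >= b` (`a` largest, `b`
smallest), the three classical estimators are evaluated exactly as
written:

    scalene  π/6 · a · b · c
    oblate   π/6 · a · a · c
    prolate  π/6 · a · b · b

The `a/b/c` assignment is a design choice: the clinical labels
("equatorial", "polar", "third diameter") do not fix an ordering, but
assigning `a` = largest and `b` = smallest makes the empirically
observed ordering of the three estimates — oblate ≥ scalene ≥ prolate —
an algebraic identity (`a·a·c ≥ a·b·c ≥ a·b·b` term by term). A
property test checks it over randomly sampled triples.

## Outcome classification

Post-treatment cases fall into three exhaustive, mutually exclusive
categories driven by the residual-fragment list: `completely_stone_free`
(no fragments), `stone_free_with_cirfs` (fragments exist, every
fragment's major horizontal axis ≤ the CIRF threshold) and
`not_stone_free` (some fragment exceeds it). The threshold defaults to
4 mm and the comparison is **inclusive** — a 4.000 mm fragment is
clinically insignificant. The rule is applied per fragment, not to the
largest fragment only; for single-fragment cases the two coincide.

The reclassification report contrasts the axis scale with the volume
scale: (i) the minimum total residual volume in the not-stone-free
group, (ii) CIRF cases whose total residual volume **strictly** exceeds
that minimum (their axis-based label understates burden), and (iii)
not-stone-free cases whose every fragment measures at or below the
threshold on axis re-measurement. Multi-fragment cases use total
residual volume for (i)–(ii) but the per-fragment maximum axis for the
CIRF rule.

On the bundled ten-fragment example (five smallest residual fragments
per group from a 72-case SWL cohort) the report finds a minimum
not-stone-free volume of 8.34 mm³, three CIRF cases above it, and three
not-stone-free fragments under 4 mm.

## Statistics

* **Pearson r** between burden measures, via the standard
  product-moment definition (scipy); undefined and rejected for
  constant vectors, n ≥ 3 required.
* **Binary logistic regression**, one univariable model per burden
  measure, outcome 1 = stone-free. The fit is Newton/IRLS on the
  2-parameter model, internally standardized for conditioning,
  converged when the largest coefficient step is < 1e-8, capped at 100
  iterations. Complete separation (diverging standardized slope or no
  convergence) is *flagged* (`converged=False`), never silently
  returned. Reported per model in the convention of clinical
  statistics packages: Wald p ("Sig"), odds
  ratio Exp(B) = exp(slope) with 95% Wald CI
  exp(slope ± 1.96·SE), and the pseudo-R²:

      R²_CS = 1 − exp((2/n)(L0 − L1)),
      R²_N  = R²_CS / (1 − exp((2/n)·L0)),

  with L0/L1 the intercept-only and fitted log-likelihoods. Predictors
  are ranked by Nagelkerke R² descending. No multiple-testing
  correction and no multivariable model, matching the univariable
  per-predictor presentation this mirrors. Tests cross-check the IRLS
  path against statsmodels' Logit and against a direct likelihood
  maximisation written independently in the test.

## The phantom generator

`render_phantom` emulates an axial CT stack containing ellipsoidal
stones of analytically known volume (π/6·d1·d2·d3, recorded to machine
precision in the manifest):

* Voxel HU = stone mean where the **voxel center** lies inside the
  (rotated) ellipsoid, else background mean; per-voxel Gaussian noise
  at the respective SD; then Gaussian blur applied in physical units.
  Noise precedes blur, mimicking reconstruction smoothing of detector
  noise. Voxel-center membership (no supersampling by default) matches
  the per-pixel behaviour of the threshold segmentation being tested; a
  supersampling flag exists for occupancy-fraction studies.
* Default HU model: background 30 ± 15, stone 800 ± 100, blur
  0.4 mm — typical renal-stone contrast, chosen as fixtures. Default
  geometry 0.7 mm pixels, 2 mm slices.

What the phantom does **not** emulate: anatomy, beam hardening,
projection/reconstruction physics, gantry tilt, non-ellipsoidal or
touching stones. Passing phantom tests therefore demonstrates the
correctness of the measurement chain (threshold → label → count →
physical units), not robustness to clinical image artefacts.

Digitization note: the voxel-count volume error of a single rendered
ellipsoid depends on where it sits relative to the voxel lattice, and
is *not* monotone in resolution for one fixed placement (a symmetric
placement can be accidentally exact). Convergence statements are
therefore made on the mean absolute error over random sub-voxel
offsets: across 4–20 mm diameters it is well within 5% at 0.5 mm
isotropic voxels and smaller again at 0.25 mm (measured ≈1% and ≈0.2%).

## The cohort simulator

`simulate_cohort` draws per-case true stone volumes from a log-normal
(defaults: log-mean 4.73, log-SD 1.1 — median ≈113 mm³, quartiles
≈62–270 mm³, matching a typical SWL referral population), generates a
random ellipsoid of that volume (log-normal axis ratios, SD 0.25, so
stones are moderately aspherical), applies multiplicative Gaussian
measurement noise (default 5%), and draws the stone-free outcome from
`logit p = intercept + slope·volume` (defaults 0.45 and −0.006 per mm³,
i.e. odds ratio ≈0.994/mm³ and ≈44% stone-free at the median volume).
Measured diameters are re-labelled after noise so the largest measured
value is reported as `a`, as an observer would. Default cohort size is
72 cases.

This simulator exists for parameter-recovery and ranking tests — the
fitted logistic model recovers the generating coefficients within their
95% CIs (coverage checked over 20 replicates at n = 2000) — not to
reproduce any particular patient cohort's statistics, which are
functions of that cohort's data.

## Numerical and I/O choices

* HU are kept floating-point after the DICOM rescale
  (`stored·slope + intercept`); no re-quantization, avoiding threshold
  edge artefacts.
* Slice thickness: the SliceThickness attribute wins; the median
  inter-slice position difference is the fallback, with a logged
  warning when they disagree by >10%.
* Slices are sorted by craniocaudal position, never by filename.
* The raw bundle (`.npy` + JSON sidecar) is content-equivalent to the
  DICOM route and exists so pipelines can skip DICOM entirely.

## Problem sizes used in the checks

The bundled test suite and the reproduction script run phantoms up to
~26 mm extent at 0.25 mm voxels (≈100³ voxels), 50 random 28×30×30
phantoms for the segmentation invariants, and 20 simulated cohorts of
n = 2000 for CI coverage; the whole suite completes in a few seconds.

## Known limitations

* Touching stones merge into one label (no watershed separation); this
  matches the behaviour of pure threshold-and-label software.
* Axis metrics are bounding-box extents; stones oriented obliquely to
  the image axes report longer axes than their true principal
  diameters, exactly as the manual along-image-axis protocol does.
* The CIRF rule uses the major horizontal axis as "fragment size";
  clinical practice is not standardized on an axis, and a different
  choice shifts borderline cases.
* Complete-separation fits report `converged=False` with whatever the
  solver last held; downstream consumers must check the flag.
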