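# Methods

`fcdsurf` implements a surface-based pipeline for automated detection of
focal cortical dysplasias (FCDs): per-vertex structural features on
cortical triangle meshes, two-stage normalization with interhemispheric
asymmetry, a shallow neural-network vertex classifier, and a
cluster-selection rule that always nominates one putative lesion per
subject.  This note documents the models, the numerical choices, and what
the synthetic testbed does and does not establish.

## Surface substrate

A hemisphere is a triangle mesh with up to three corresponding surfaces
(white = grey/white interface, pial, inflated), sharing vertex count and
face list, FreeSurfer-style.  All coordinates are in mm and all vertex
indices 0-based.  The medial wall is excluded everywhere through a
per-vertex cortex mask: masked vertices never enter geodesic
neighbourhoods, smoothing, statistics or training.

**Geodesic distance.** Neighbourhoods (the 6 mm doughnut disc, the 25 mm
LCD disc) use Dijkstra shortest paths on a *chord-augmented* vertex graph:
besides mesh edges, every vertex is connected to all vertices within
`k = 3` hops, weighted by the 3D chord length.  Plain edge-graph Dijkstra
induces a strongly anisotropic metric (on a unit grid with one diagonal
per cell, discs come out 10–23% smaller than `pi*r^2`); with 3-ring
chords the worst-case directional overestimate on a flat grid drops to
~1.3%, so a 6 mm disc on a 1 mm mesh covers ~113 mm^2 to within a few
percent.  Chords span at most ~3 edge lengths, so the shortcut error
through curved regions stays below the mesh resolution at the radii used
here.  This remains an approximation; exact polyhedral geodesics are out
of scope.

**Equal-area annulus.** The doughnut's surrounding annulus is grown
outward vertex-by-vertex in distance order and stopped at the first
crossing of the inner-disc area, so its area exceeds the disc's by at
most one vertex-area increment.  This rule is deterministic and adapts to
mesh resolution.

**Smoothing.** Gaussian smoothing with full width at half maximum `fwhm`
is implemented as heat diffusion for time `t = sigma^2/2` with
`sigma^2 = fwhm^2/(8 ln 2)`, using the cotangent Laplace–Beltrami
operator with barycentric vertex areas and explicit Euler steps bounded
by the stability limit (iteration count `= t/step`, i.e. the calibration
is analytic, not an empirical lookup table).  Negative cotangent weights
are clipped to zero for monotonicity.  The operator has zero row sums, so
constants are preserved exactly and the area-weighted sum is conserved to
float precision on closed meshes; the measured half-maximum radius of an
impulse response on a flat grid matches `fwhm/2` to a few percent.

## Features

* **Thickness**: mean of the two directed vertex-to-surface minimum
  distances between white and pial, computed exactly over candidate
  triangles found via a k-d tree (k = 6 nearest vertices, all incident
  faces).
* **Grey-white contrast**: T1 intensity at 30% of the cortical thickness
  above the grey-white boundary divided by the intensity 1 mm below it
  (along the inward white-surface normal); trilinear interpolation.
  Boundary blurring moves the ratio toward 1.
* **FLAIR depth profile**: samples at the boundary, 25/50/75% thickness,
  and 0.5/1 mm below the boundary (six maps).
* **Intrinsic curvature**: discrete Gaussian curvature as the angle
  deficit `2*pi - sum(angles)`; the deficits of a closed genus-0 mesh sum
  to `4*pi` exactly (Gauss–Bonnet), which every generated mesh is tested
  against.  Boundary vertices are flagged non-finite.
* **Local cortical deformation (LCD)**: sum of |angle deficit| over the
  25 mm geodesic disc on the pial surface.  On a sphere of radius R the
  expected value is the absolute total curvature of the cap,
  `2*pi*(1-cos(r/R))`.  The sum is taken over a filled disc; a hollow
  "ring" mode (`mode="ring"`, configurable width) is provided as an
  alternative reading of the neighbourhood shape.
* **Doughnut maps**: per vertex, a two-sided Welch t-test compares a
  feature between the 6 mm disc and its equal-area annulus; the map value
  is the *signed* `-log10 p` (positive where the disc mean is higher —
  the sign distinguishes local thickening from thinning), then smoothed
  at 10 mm FWHM.  Welch rather than pooled-variance t because the lesion
  core and its surround cannot be assumed homoscedastic.  Vertices
  contributing fewer than 3 samples to either group get 0.  The
  vectorised implementation is verified against `scipy.stats.ttest_ind`
  on hundreds of random cases to 1e-9.

Doughnut maps are computed on features that were themselves pre-smoothed
at 10 mm, and the doughnut output is smoothed again at 10 mm; either
smoothing can be disabled in the configuration.

## Normalization and the 28-column matrix

Per subject and feature: (1) quantification (thickness, contrast and the
FLAIR samples smoothed at 10 mm FWHM), (2) within-subject z-scoring over
cortex vertices (removes per-individual offset and scale), (3) vertex
correspondence to the symmetric template — abstracted as an explicit
bijective left-right vertex table; the synthetic hemispheres are built
mirror-symmetric so the identity map is exact, while real data require an
externally computed (xhemi-style) correspondence — (4) interhemispheric
asymmetry of the z-maps (`left asym = z_L - z_R(corr)`, and vice versa;
positive = ipsilateral larger), and (5) per-vertex normalization of both
z-maps and asymmetry maps by the healthy-control mean and SD.

Doughnut maps stop after step 2 (they are already local contrasts);
sulcal depth and mean curvature are z-scored but not control-normalized
(they enter as plain regional descriptors, and both choices are
switchable per feature).  The control-SD floor is 1e-6 of the feature's
cohort-median SD; vertices below it map to 0 rather than blowing up.

The canonical 28 columns, in order: z-thickness, z-contrast, sulcal
depth (z), mean curvature (z), six z-FLAIR samples, z-LCD, doughnut
thickness, doughnut contrast, six doughnut FLAIR, and the asymmetries of
thickness, contrast, the six FLAIR samples and LCD.  Labels: lesional
vertices 1, contralateral-hemisphere cortex 0, ipsilateral non-lesional
vertices excluded from training (lesions may extend beyond the visible
mask); controls contribute no labelled rows.

## Classifier

A single-hidden-layer feedforward network (logistic activations, output
in [0, 1] read as lesion probability), built over scikit-learn's
`MLPClassifier` inside a sklearn-style estimator (`fit` /
`predict_proba`, seeded and bitwise reproducible).  The hidden-layer
width is the smallest number of principal components explaining > 99% of
the variance of the standardized control-cohort features; single-feature
networks use 2 hidden nodes so both abnormally high and low values can be
captured.  Inputs are standardized with training-fold statistics only.
Training uses Adam with batch size 512 and an epoch count targeting a
fixed number of gradient updates (small fixtures get many epochs, large
vertex tables few), with a loss-plateau stop.  Class imbalance (tens of
lesional rows against tens of thousands of healthy rows) is left as-is by
default; an optional flag balances classes by seeded minority
oversampling.  Evaluation is leave-one-patient-out: control statistics
and the PCA node count are computed once from controls, and each fold's
training rows exclude the held-out subject (asserted in tests).

## Detection rule

Per subject, the probability map over both hemispheres' cortex vertices
is thresholded to the top 5% (pooled across hemispheres by default;
per-hemisphere mode available), survivors are grouped into
edge-connected clusters, clusters below the minimum size are dropped, and
the cluster with the highest mean probability is the putative lesion;
detection succeeds if it overlaps the lesion mask.  The size floor is 200
vertices at full FreeSurfer resolution (~1 cm^2); because synthetic
meshes are coarser, the pipeline defaults to the equivalent areal floor
of 100 mm^2 (the vertex-count mode remains available).  Ties are fixed
deterministically: threshold ties break toward the lower vertex index,
equal cluster means toward the larger cluster, then the lower minimum
vertex index.  All clusters are reported ranked, so rank-k analyses (e.g.
"found as the 5th cluster") are possible.  One cluster is always
nominated when any survive; specificity is therefore undefined by design.

## Synthetic cohorts

Hemispheres are spherically parameterized closed surfaces: a base sphere
(55 mm radius, icosphere level 5, 10,242 vertices, ~8,700 cortex vertices
after masking a 45-degree medial-wall cap) carrying band-limited radial
folding waves (SD 2.5 mm, wavelengths 24–40 mm).  The pial surface is the
white surface displaced outward by a smooth thickness field (base
2.5 mm); the inflated surface is the undisplaced sphere; the right
hemisphere is the mirrored left, so the interhemispheric correspondence
is exactly the identity.  Genus-0 construction makes Gauss–Bonnet an
exact mesh test.  T1 and FLAIR volumes are rendered analytically from the
same radial functions (WM/GM/background plateaus, 1.2 mm boundary blur,
voxel 1.5 mm, additive voxel noise), so volume sampling and surface
geometry are mutually consistent.

**Variance bookkeeping.** Inter-subject variability of each feature is
split into a bilaterally *shared* smooth field and a per-hemisphere
*independent* smooth field of equal variance, plus fine-scale measurement
noise.  With that split a unilateral effect of `k` control-SD expresses
close to `k` both in the control-normalized feature z-maps and in the
control-normalized asymmetry maps (the shared variance cancels from the
asymmetry, the factor-of-two from differencing is offset by the halved
variance).  Lesion effect sizes are therefore specified in control-SD
units and converted to raw units analytically from the wave amplitudes,
including (a) the attenuation of the subject fields under the pipeline's
10 mm smoothing (computable per wavelength) and (b) the erosion of the
implanted plateau profile under the same smoothing (a planar convolution
integral evaluated numerically in the generator).  Small residual biases
remain — the 1/SD estimator from 10 controls is ~9% high in expectation,
and the thickness measurement picks up a local metric factor from the
folding — and are visible as recovered effects a tenth of an SD or so off
the configured value.

**Implanted lesions** are geodesic discs (default radius 8 mm with a 5 mm
soft shoulder; the mask is the plateau): thickness shifted by +2
control-SD, the grey-white ratio moved toward 1 (boundary blurring) by
2 SD, FLAIR raised by 2 SD across the grey matter and the superficial
1.5 mm of white matter, and a high-frequency pial ripple (0.3 mm
amplitude, 10 mm wavelength) confined to the lesion that raises LCD.
Zero-amplitude effects reproduce the healthy subject exactly.

**Confounds** present in every subject: a bilateral thin patch
(somatosensory analogue — extreme within-subject z-thickness, near-zero
asymmetry), a left-only thick patch (planum-temporale analogue — nonzero
raw asymmetry that control normalization filters out), and one random
unilateral FLAIR blob per subject at 2 control-SD (motion-artifact
analogue; it carries a FLAIR-only signature, unlike the multi-feature
lesion signature).

**What the testbed does not show.** Folding is statistically band-limited
noise, not gyral anatomy; registration error is absent by construction
(identity correspondence); artifacts are additive blobs rather than
ringing or bias fields; all lesions share one effect profile.  Passing
the end-to-end checks therefore demonstrates internal consistency and
direction-of-effect behaviour of the method, not clinical performance.

## Problem sizes and runtime choices

The default study conditions for the end-to-end analysis are 10 controls
and 8 patients at ~8,700 cortex vertices per hemisphere, with 2-SD
lesions, evaluated on cohort seeds 1–5 — chosen so the full feature
extraction plus two LOOCV runs (all 28 features, and the 10 established
features) complete in a few minutes per cohort on one CPU.  The paper-
scale mesh (~150k vertices/hemisphere) is reachable through
`CohortSpec(subdivisions=7)` for stress tests.  `scripts/acceptance.py`
averages the end-to-end quantities over 2 cohort seeds derived from its
`--seed` argument.

## Known limitations

* Graph geodesics (even chord-augmented) overestimate distance slightly
  anisotropically; disc areas are accurate to a few percent, not exact.
* The symmetric-template registration is consumed as a correspondence
  table, never computed; real-data use needs FreeSurfer xhemi or
  equivalent.
* Sulcal depth and mean curvature are consumed as inputs (synthetic
  stand-ins here); no inflation or curvature-flow machinery is included.
* The per-vertex doughnut t-test treats vertices as independent samples;
  areal weighting is not implemented.
* With 10 controls the per-vertex control-SD estimate is noisy; recovered
  z-effects at single locations scatter by several tenths of an SD, and
  only cohort means are calibrated.
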