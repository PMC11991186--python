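# Methods

## Model

Planning a rigid-needle trajectory is cast as an illumination problem: a
point source at the puncture target emits rays through a labelled anatomy
volume, and the brightness that survives to the needle-length sphere scores
each candidate direction.  The analogy is exact for the constraints that
matter: light travels in straight lines (rigid needle), opaque voxels block
it entirely (hard obstacles), translucent voxels attenuate it in proportion
to the path length through them (soft risk accumulation), and diffuse
reflection off the skin encodes the insertion-angle preference.

**Beer–Lambert accumulation.**  Each label maps to an optical role.
Absorbing labels carry a per-mm coefficient k; along a ray the absorbance
per class is A = Σᵢ kᵢ·lᵢ with lᵢ the chord length through voxel i, and the
transmitted fraction is 10^(−A).  Two absorbing classes are tracked
separately so each soft constraint survives as its own channel: ordinary
soft tissue (default k = 0.02 mm⁻¹ — the attenuation surrogate for
insertion depth) and pulmonary vessels (default k = 0.1 mm⁻¹ — accumulated
vessel thickness, so many or thick vessels darken a direction without any
explicit vessel geometry processing).  Background, and the target lesion
itself, are transparent.

**Hard constraints.**  Bones, heart, airways and non-target lobes are
opaque.  Before casting, the opaque mask is dilated by a Euclidean ball of
radius `obstacle_margin_mm` (default 2 mm), so any surviving direction
clears the original obstacles by at least that margin; the exact Euclidean
distance transform to the *un-dilated* obstacles is kept so the guarantee
remains independently checkable on every emitted path.  A direction is
feasible (Iobs = 1) iff its ray reaches a skin voxel within the needle
length R without touching the dilated opaque mask, and does not re-enter
interior tissue after first leaving the body (a ray through an arm fold or
skin crease is rejected; merely brushing further surface voxels after exit
is not a re-entry, since the needle tail outside the body may graze the
skin).  A ray that leaves the body without ever touching a skin voxel is
conservatively infeasible — skin missing from the scan means the entry
point cannot be verified.

**Skin angle.**  At the skin entry the Lambertian term
Aref = max(0, cos θ) uses the outward skin normal estimated from the
gradient of the Gaussian-smoothed body mask (σ = 2 voxels, trilinear
interpolation at the entry point).  σ = 2 was chosen because σ = 1 leaves
enough voxelization anisotropy to tilt normals by up to ~8° against the
analytic normal of a digitized sphere; σ = 2 keeps them within ~4°.
Degenerate (zero-gradient) points fall back to the ray direction.

**Composition.**  Per direction,

    I = Iobs · Atra^α · Aref^β · Avas^γ ,   0⁰ ≡ 1 ,

with α = β = γ = 1 by default (exposed in the tissue config).  All three
attenuation terms are natively in [0, 1]; the transmitted fraction itself is
the normalization (A = 0 ⇒ term = 1 ⇒ no penalty).  Larger exponents make
the score more sensitive to the corresponding constraint.  Insertion depth
is regulated implicitly: depth ≤ R is enforced by the shell radius and
longer tissue traversal lowers Atra; no separate depth window is imposed.

## Ray casting

Rays are cut exactly at voxel faces: the per-axis face crossings of a
straight ray form arithmetic sequences, so a whole batch of rays is
traversed by generating the three sequences, sorting them jointly, and
classifying each inter-crossing segment by the voxel containing its
midpoint.  Line integrals over the piecewise-constant label field are
therefore exact up to float rounding — there is no sampling step to tune —
and the tests compare them against independent dense-sampling oracles.
Zero-length segments (corner touches) are ignored for classification, since
the continuous path spends no length in those voxels.  Early ray
termination (stop at the first opaque segment) and empty-space skipping
(no accumulation over zero-coefficient runs) are pure optimizations; a
toggle test asserts they change no output beyond 1e−12.  Fixed-step
midpoint marching remains available (`cast_ray(step_mm=...)`) for
comparison studies.

The shell is a lat–lon grid (default 1°, i.e. 181 × 360 directions;
`resolution_deg` must divide 180).  The polar axis is superior (+z), the
zero meridian anterior (−y, the patient's front — CT beds are posterior),
both configurable through `SphereFrame`.

## Projection and regions

The sinusoidal projection x = λ·cos φ, y = φ is equal-area: every valid
pixel at resolution r subtends r² square degrees, so region pixel counts
are proportional to solid angle and 2D region sizes are comparable.  Pixels
are assigned the nearest shell node of their back-projected direction,
making pixel → direction → pixel round trips exact to well under half a
pixel.  Channels: R = Avas, G = Atra, B = Iobs·Aref (feasibility folded
into blue, so B > 0 ⇔ feasible).

Candidate regions are 8-connected components of the thresholded image
(defaults: B > 0 required; G ≥ 0.05; R ≥ 0, i.e. vessels penalize through
intensity rather than exclusion) with area ≥ `min_area` (default 25 px at
1°, ≈ 25 deg² of solid angle; scale by the squared resolution ratio at
other grids, e.g. 3 px at 3°).  Each region yields a fixed, ordered
50-entry feature vector (`regions.FEATURE_NAMES`): 17 geometry descriptors,
7 Hu moments + 7 central moments, 15 per-channel intensity statistics, and
4 position-relative-to-centre entries.  The list is versioned
(`FEATURE_VERSION`); persisted models embed it and refuse to predict across
versions.  The chosen region is reduced to its entry pixel by iterated 3×3
binary erosion, returning the surviving pixel nearest the centroid of the
last non-empty set (ties: smallest row, then column) — always a member of
the original region, always deterministic.

## Recommender

Regions from many images form a grouped, imbalanced binary dataset (one
preferred region among several per image).  Splits are by image
(7 : 1 : 2 by default) so no image's regions straddle subsets.  The
training split only is balanced to class parity by SMOTE-style
interpolation between minority nearest neighbours (implemented in-package
over scikit-learn's NearestNeighbors).  The default model is a 100-tree
random forest, depth 10, `class_weight="balanced"`; gradient boosting and
four MLP layouts (100; 100–50; 200; 150–75–30, ReLU/Adam, ≤300 iterations)
sit behind the same interface.  Evaluation reports AUC-ROC, precision,
recall, F1, specificity and the confusion matrix on held-out groups.  At
inference the highest-probability region wins (ties: larger area, then
centroid nearest the image centre); `plan_path(manual_region=...)` bypasses
the classifier for manual selection, and with no model a transparent
area × mean-green heuristic ranks regions.

Reported path metrics: depth = |entry − target|; skin angle is given
relative to the skin *plane* (90° − θ, so steeper is larger, matching
clinical convention) while the Lambertian model itself uses θ from the
normal; minimum obstacle distance is the minimum of the exact distance
transform (to un-dilated obstacles) sampled every quarter voxel along the
path.

## Synthetic phantom and annotation rule

The phantom emulates the label vocabulary of a thoracic segmentation —
body, 1-voxel skin shell, two lungs with 2–5 lobe compartments (most
anterior compartment of the host lung holds the nodule), 2-level branching
vessel trees with graded radii, closed rib rings following the body
cross-section, an opaque heart blob, an airway tube, and a spherical nodule
placed in the deepest quintile of the target lobe.  Geometry is parametric
(ellipsoids and capsules) and bit-reproducible given the seed; each draw is
accepted only if a brute-force ray sweep finds an obstacle-free corridor
from nodule to skin, otherwise the geometry is re-drawn deterministically.
Rib rings are closed so that each intercostal window projects to its own
candidate region, giving the classifier a genuinely multi-region,
imbalanced task (≈ 4–6 regions per image, exactly one positive).

Defaults: 64³ voxels at 2.5 mm (a 160 mm thorax) with a 6 mm nodule, 4 mm
ribs and 3/2/1.3 mm vessel levels.  Tests also use a miniature 48³ @ 1 mm
phantom with proportionally scaled structures (2 mm ribs, 3 mm nodule,
2/1.4/1 mm vessels, 3 ribs) where a small instance is needed for exhaustive
oracles.

The rule-based annotator stands in for surgeon preference: the positive
region maximizes area × mean green intensity (large windows with little
tissue to traverse), ties broken toward the image centre, then list order;
an optional seeded label-flip rate supports robustness experiments.  The
rule is deliberately simple, fixed and documented so that classifier
recovery is a measurable quantity rather than an article of faith.

**What the phantom does not emulate**: real thoracic topology (fissure
geometry, mediastinal anatomy, arm positioning), CT intensities and
segmentation errors, respiratory motion, and real surgeon preferences —
which weigh factors (accessibility, lesion character, patient posture) the
annotation rule does not encode.  Passing tests therefore demonstrate the
pipeline's geometric and statistical correctness and the learnability of a
consistent preference signal, not clinical performance on patients.

## Numerical choices and scales

* World coordinates are mm, voxel-center convention, 0-based indices;
  volumes must be axis-aligned (identity direction matrix) and are
  resampled to isotropic spacing (smallest input spacing, nearest-neighbour)
  before planning.
* The ROI is the exact centred cube of side 2·⌈R/spacing⌉ + 1 with the
  target at the centre voxel; out-of-image regions are zero-padded and
  flagged invalid, as are voxels outside the R-sphere.
* Obstacle dilation uses the distance-transform threshold `d ≤ margin`,
  always relative to the original obstacles (re-dilation replaces, never
  compounds).
* Shell chunking (default 8192 rays) does not affect any value; the map is
  deterministic and thread-count independent.
* Problem sizes used by the test-suite and the acceptance script: 3°
  shells and R = 153 mm for end-to-end planning on 64³ phantoms; 5°
  shells and R = 20 mm for exhaustive direction-set oracles on the 48³
  miniature; a 200-image corpus (grouped 150/50 split) for classifier
  recovery.  These are the package's standard benchmark sizes; all scale
  up by raising the resolution and grid parameters.

## Known limitations

* Only axis-aligned label volumes are accepted; oblique acquisitions must
  be resampled upstream.
* The skin-angle term uses the smoothed-mask normal; on very coarse grids
  (≳ 3 mm) normals near thin structures can tilt several degrees.
* The minimum-obstacle-distance metric is voxel-resolution limited: it is
  exact for voxel centers along the walked path, so sub-voxel clearance
  beyond the guaranteed margin is approximate.
* `unproject_pixel` assumes the default anterior/north frame; shells built
  with a custom `SphereFrame` should be unprojected through that frame.
* The recommender learns whatever annotation signal it is given; with the
  built-in rule the task is nearly separable and held-out AUC approaches 1,
  which is a property of the rule's simplicity, not a clinical claim.
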