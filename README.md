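# lumipath

Optical-illumination path planning for CT-guided percutaneous rigid-needle
biopsy.

## The problem

A rigid biopsy needle travels in a straight line from a skin entry point to a
target (typically a lung nodule).  A safe trajectory must not cross bone, the
heart, the airways or a non-target lung lobe; it must stay clear of obstacles
by a margin, be shorter than the needle, and ideally be short, steep to the
skin and avoid large vessels.  Searching 3D space for such an entry point is
the planning bottleneck of CT-guided interventions, where every minute of
computation risks patient motion invalidating the plan.

`lumipath` reframes the search as a lighting computation.  A virtual point
light source sits at the target inside a labelled anatomy volume.  Each
tissue class gets an optical role: hard obstacles are **opaque**, safe soft
tissue **absorbs** lightly (k = 0.02 mm⁻¹), pulmonary vessels absorb more
strongly (k = 0.1 mm⁻¹), and background and the target itself are
transparent.  Along each direction the Beer–Lambert law accumulates
absorbance A = Σᵢ kᵢ·lᵢ per class, giving transmitted fractions
Atra = 10^(−A_tissue) and Avas = 10^(−A_vessel).  The insertion-angle
preference enters as Lambertian shading of the skin, Aref = max(0, cos θ)
with θ the angle between the ray and the outward skin normal.  Each
direction on the needle-length sphere then scores

    I = Iobs · Atra^α · Aref^β · Avas^γ

where Iobs ∈ {0, 1} indicates the direction is unobstructed, reaches skin
within the needle length R, and clears every (margin-dilated) obstacle; the
exponents α, β, γ encode clinician preferences.  Bright directions are
feasible, preferable trajectories.

The sphere is flattened by an equal-area sinusoidal projection into an RGB
image (R = Avas, G = Atra, B = Iobs·Aref) whose connected bright regions are
candidate entry windows.  A classifier trained on annotated regions — a
100-tree, depth-10 random forest with balanced class weights by default,
after SMOTE oversampling of the scarce positive class — picks the region a
surgeon would, the region is eroded to a single pixel, and that pixel is
mapped back to a 3D skin entry point, yielding the final trajectory with its
clinical metrics (depth, skin angle, minimum obstacle clearance).

Because real CT masks and surgeon annotations cannot be shipped, the package
includes a seeded synthetic thorax phantom (body + skin shell + lobed lungs +
branching vessels + rib rings + heart + airway + nodule) and a fixed,
documented annotation rule, so the entire pipeline — including classifier
recovery — is testable from nothing but a seed.

## Worked example

```python
import numpy as np
from dataclasses import replace
import lumipath as lp

spec = lp.PhantomSpec(seed=1)                       # 64³ @ 2.5 mm thorax
vol = lp.generate_phantom(spec)
cfg = replace(lp.default_tissue_config(spec), min_area=3)
nodule = np.argwhere(vol.labels == spec.labels["nodule"])
target = vol.index_to_world(nodule.mean(axis=0))

result = lp.plan_path(
    vol, lp.NeedleQuery(target=target, needle_mm=153.0), cfg, resolution_deg=3.0
)
p = result.path
print(f"insertion depth:       {p.depth_mm:.1f} mm")
print(f"angle to skin:         {p.skin_angle_deg:.1f} deg")
print(f"obstacle clearance:    {p.min_obstacle_distance_mm:.1f} mm")
print(f"candidate regions:     {len(result.regions)}")
print(f"feasible directions:   {result.shell.iobs.mean():.1%} of the shell")
```

prints

```
insertion depth:       18.0 mm
angle to skin:         85.1 deg
obstacle clearance:    7.5 mm
candidate regions:     5
feasible directions:   47.2% of the shell
```

i.e. the planner found a straight 18 mm path entering almost perpendicular
to the skin and staying 7.5 mm away from the nearest bone/heart/airway/
other-lobe voxel — comfortably above the 2 mm hard margin.  (Depths are
phantom-scale: the synthetic thorax is a 160 mm cube.)  `result` also
carries the full audit trail: the illumination shell, the RGB projection,
all candidate regions with their 50-entry feature vectors, and the chosen
entry pixel.

The same pipeline is available from the shell:

```sh
lumipath phantom --out vol.nii.gz --size 64 --spacing 2.5 --seed 1
lumipath plan --volume vol.nii.gz --target 113.8,44.7,101.2 \
    --needle-mm 153 --config tissue.yaml --out report.json
lumipath train --features features.csv --labels labels.csv --out model.joblib
```

## Layout

| module | role |
| --- | --- |
| `volume_io` | NIfTI/NRRD label volumes, isotropic resampling, tissue-role config |
| `phantom` | seeded synthetic thorax + rule-based region annotator |
| `roi` | needle-length cube crop, no-skin direction removal |
| `optics` | absorption field, obstacle dilation, exact ray casting, shell map |
| `projection` | sinusoidal equal-area RGB projection and its inverse |
| `regions` | thresholding, connected regions, 50 named features, entry-pixel erosion |
| `recommend` | grouped splits, SMOTE balancing, classifiers, end-to-end `plan_path` |
| `corpus` | phantom corpora for classifier training/evaluation |
| `cli` | `lumipath phantom / plan / train` |

See `docs/methods.md` for the model, its assumptions, parameter defaults and
known limitations.
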