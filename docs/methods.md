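# Methods

This note records the models, parameters and design decisions behind
`corseg`, and what its synthetic-phantom validation does and does not
establish.

## Problem setting

The package segments 18 cardiac structures on radiotherapy-planning CT:
four chambers (LA, LV, RA, RV), three great-vessel bases (AA, PA, SVC),
four valves (AV, PV, MV, TV), four coronary arteries (LAD, LCX, LMCA,
RCA) and two conduction nodes (AVN, SAN). The whole heart (WH) is assumed
given — it is the one structure routinely contoured in thoracic
radiotherapy, and deep-learning WH segmentation is mature — so the
pipeline takes a WH mask (file or pluggable backend) and never retrains a
WH model. Everything operates in world millimetres with a voxel-centre
convention; all algorithm parameters are physical (mm), never voxel
counts, so behaviour is resolution-independent.

## Stage 1–3: whole-heart-guided multi-atlas mapping

**Why distance maps.** Atlas CT intensities differ from the target
(contrast agent, artefacts, dose), so the first two stages register
*normalised signed distance maps* of the WH masks instead of images:
signed Euclidean distance, negative inside, divided by the maximum
interior depth so the deepest point of any heart sits at −1. This makes
hearts of different sizes commensurate and focuses the alignment on the
cardiac volume. Signed (not interior-only) maps are used so the zero
level set — the WH boundary — carries gradient information on both sides.
Internally the normalised maps are multiplied by 100 before demons
registration, keeping differences above ITK's intensity-difference floor;
the demons update is invariant to this common scale.

**Affine stage.** SimpleITK's registration framework with mean-squared
difference, regular grid sampling at rate 0.75 (deterministic — no seed
needed), gradient-descent line search, 50 iterations per level, and
shrink factors 16/8/4 (clamped so no level drops below ~4 voxels per
axis). Initialisation is centroid (moments) alignment of the two masks,
which the optimiser needs when hearts start far apart. If the metric
increases across an entire level the stage raises a diagnostic error
rather than returning a diverged transform.

**WH-guided deformable stage.** A demons-style registration
(symmetric-forces filter, Gaussian field regularisation of 1.5 voxels) of
the two normalised distance maps over fixed isotropic levels 16/8/3 mm,
50 iterations each, each level initialising the next. Because the moving
and fixed images are normalised *depth* fields, matching their
intensities drives every iso-depth surface — not just the boundary — into
correspondence: the warp co-registers the WH boundary (phantom tests
reach DSC ≥ 0.98 sphere→ellipsoid) and approximately preserves relative
interior depth (|Δdepth| ≤ 0.1 at sampled iso-depth surfaces down to
−0.75). The depth-preservation *post-condition* is the contract; the
specific regulariser is an implementation choice.

**Restricted demons stage.** Diffeomorphic demons (SimpleITK's
`DiffeomorphicDemonsRegistrationFilter`; the closest installed variant to
log-domain symmetric-forces demons) on the CT intensities over isotropic
levels 6/3/1.5 mm with 200/150/100 iterations, run inside the bounding
box of the target WH dilated by 20 mm ("the vicinity of the heart" made
concrete). The resulting update is zeroed outside the dilated-WH region,
so outside it the transform is identically the initialisation; the
Jacobian determinant must be positive throughout the region or the stage
errors. Field smoothing is Gaussian with sigma 2.5 mm at the finest level
(scaled with level voxel size). The stronger-than-usual regularisation is
deliberate: cardiac deformations between patients are smooth, the blood
pool is homogeneous (the field there must be interpolated from boundary
evidence), and phantom recovery experiments showed smoother fields track
the true deformation better (mean error 1.85 mm vs 2.01 mm at sigma
1.5 mm). An optional HU window (e.g. [−250, 500]) can be applied before
this stage; it is off by default.

Warped masks use linear interpolation of the binary mask followed by a
0.5 threshold, which lands the warped boundary with sub-voxel accuracy.
The composite transform applies, to a target point, the demons field,
then the structure-guided field, then the affine (function composition
affine ∘ structure-guided ∘ demons), and equals the sequential
application of its stages to < 1e-3 mm.

## Label fusion and thresholds

Fusion is unweighted voting: the probability at a voxel is the fraction
of atlases labelling it. Thresholds are searched on the fixed grid 0.05,
0.10, …, 0.95 (ties broken toward 0.5) to minimise the mean absolute
relative volume difference against reference volumes, leave-one-out: the
probability map scored for a case never contains that case's own
contours, and in the nested form used for evaluation the threshold
applied to a case is chosen without that case's reference. Volume ratio
is the objective because systematic volume bias is what distorts dose
metrics. Within `run_case`, "optimise" mode runs the leave-one-out
procedure over the warped atlas masks already in target space (each
warped atlas in turn as pseudo-reference), avoiding a quadratic number of
extra registrations; the standalone `optimise-thresholds` command applies
the same procedure to an atlas cohort by direct fusion.

Post-processing keeps each structure's largest 26-connected component,
fills holes (6-connected background), then assigns every overlap to the
larger structure, processing pairs in descending volume order. The
cleanup+overlap pass is iterated to a fixed point (≤ 5 passes) because
subtracting an overlap can split the smaller structure; this makes the
operation idempotent in practice. Valves are deliberately *not* made
disjoint from the chambers and vessels that define them — anatomically
they occupy the same voxels — so disjointness is enforced only among the
seven multi-atlas structures.

## Geometric models

All constructions are deterministic functions of the masks and
parameters, with guideline defaults: AV/PV slab thickness 8 mm, MV/TV
cylinder 30 mm diameter × 8 mm thickness, coronary tube diameter 4 mm,
node sphere radius 10 mm.

* *Semilunar valves*: `(dilate(ventricle, t) \ ventricle) ∩ vessel`. A
  vessel that never meets the dilated shell is a construction error.
* *Atrioventricular valves*: a voxelised cylinder centred on the
  atrium–ventricle junction (centroid of interface voxels, computed after
  2 mm mutual dilation if the raw 6-neighbour interface is empty), with
  its axis along the chamber-centroid difference. The axis sign is
  canonicalised and the centre given a 1e-3 mm axial offset so swapping
  the argument order yields the identical voxel set and end planes that
  align exactly with voxel centres are not counted on both faces.
* *Coronary arteries*: fuse the warped atlas tubes, threshold at 0.5
  (falling back to the maximum-probability ridge), skeletonise in 3D,
  take the longest (graph-diameter) path through the 26-connected
  skeleton weighted by physical edge length, fit a cubic smoothing spline
  (`splprep`, smoothing 2 × number of path points), and sweep a 4 mm
  sphere along it, keeping the largest component.
* *AVN*: sphere centred on the voxel minimising the summed unsigned
  distances to the four chamber surfaces; an error if that minimum
  exceeds 50 mm (no plausible junction).
* *SAN*: sphere at the SVC–RA interface centroid, walked along the
  steepest-inward gradient of the WH signed distance until the continuous
  containment condition d(centre) ≤ −r holds, then nudged for the
  discrete voxelisation. If the walk stalls (thin or ridged hearts), the
  centre falls back to the deep-enough voxel nearest the junction; if the
  WH nowhere reaches depth r, the construction errors.

## Synthetic phantom

The generator emulates a thoracic planning CT at clinical resolution
(default 128×128×80 voxels at 2×2×2.5 mm): soft tissue ≈ 30 HU, lungs
≈ −750 HU, myocardium shell ≈ 50 HU, blood pool ≈ 40 HU, plus Gaussian
noise of 10 HU (a typical planning-CT noise level; set once). The heart
is four ellipsoidal chambers in anatomical arrangement (overlaps resolved
by nearest-in-ellipsoid-metric assignment, giving curved septa), vessel
tubes abutting the correct chambers (AA–LV, PA–RV, SVC–RA) so valve and
node constructions have valid junctions, and 4 mm coronary tubes on the
epicardial surface (rasterisation radius floored at one voxel so the
tubes stay resolvable on coarse grids). WH is the union of all components
dilated by 3 mm. Anatomy is defined on a 256×256×200 mm reference extent
and rescaled to other grids.

Atlas cohorts warp the noiseless template with random smooth displacement
fields: displacements drawn on a 40 mm control grid (zeroed at the
boundary), cubic-upsampled, scaled to a maximum of 8 mm, rejected and
shrunk if the Jacobian determinant is not strictly positive. Case *i*
depends only on (master seed, *i*), so cohorts are prefix-stable, and the
true field is retained on each case for recovery tests.

What the phantom does *not* emulate: CT texture and beam-hardening
artefacts, respiratory/cardiac motion blur, contrast enhancement, and
real inter-patient anatomical variation (its "patients" are smooth
deformations of one template). Passing the phantom tests therefore
demonstrates the algorithmic contracts — recovery of known smooth
deformations, depth preservation, threshold behaviour, geometric
fidelity — not clinical-grade accuracy on patient data.

## Validation problem sizes

The clinical parameter defaults are used throughout; validation scales
the *data*, not the method. Registration-recovery checks run on the
default 128×128×80 phantom with the final demons level at 2 mm; the
end-to-end and threshold-optimisation checks use a 64×64×48 phantom at
3 mm with shortened level schedules (two levels, 20–30 iterations),
which keeps the full 10-case × 9-atlas cross-registration around two
minutes on one CPU. The distance-preservation check uses a 2 mm
sphere→ellipsoid pair; geometric-parameter checks use 1 mm isotropic
grids, where one voxel equals 1 mm.

## Known limitations

* DICOM-RT STRUCT import/export is not implemented; structure sets are
  per-structure NIfTI volumes (DICOM *image* series are readable).
* The WH-guided stage's depth preservation is empirical (±0.1 normalised
  depth on test geometry), not a mathematical guarantee.
* Zeroing the demons update outside the dilated WH introduces a field
  discontinuity at the region boundary; the 20 mm margin keeps it away
  from the structures of interest, and the Jacobian check covers the
  region interior.
* Coronary and valve constructions assume the multi-atlas stage produced
  anatomically sensible chambers and vessels; they propagate, rather than
  correct, upstream segmentation error.
* Threshold optimisation applies only to the seven multi-atlas
  structures; WH, valves, arteries and nodes have no threshold to tune.
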