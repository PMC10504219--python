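# Methods

`mammoplan` implements a computational surgical-planning chain for
breast-conserving therapy. The clinical problem it addresses: breast MRI is
acquired prone (the breast hangs anteriorly in the coil), but lumpectomy is
performed in the supine-surgical position (SS), where gravity loads the
tissue posteriorly — so the tumor the radiologist localised is no longer
where the surgeon will look. The chain fuses MRI-derived anatomy with
multi-pose surface scans, simulates the pose change mechanically, trains a
neural surrogate that can replace the per-patient simulation, and exports a
printable model with the tumor highlighted. Because no patient data ships
with the package, every stage is exercised on parametric synthetic subjects
("phantoms") generated by `mammoplan.phantom`.

## Coordinate and unit conventions

All lengths are millimetres in a right-handed torso-fixed frame: +x left,
+y superior, +z anterior. Young's moduli are kilopascals, densities
kg/m³, gravity m/s² (9.81 by default); internally the FE solver works in
N and mm (1 kPa = 10⁻³ N/mm²; ρg = 10⁻⁹ N/mm³ per unit volume). Voxel
grids are 0-based with the centre of voxel *i* at `origin + (i + 0.5) ·
spacing`. Pose gravity directions in the torso frame: PRONE = +z, SS and
SU = −z, standing = −y. Arm-position differences between the supine poses
are deliberately not modelled beyond the gravity direction — no
musculoskeletal model is attempted.

## Synthetic subjects

A phantom is a half-superellipsoid breast (semi-axes `a, b, c`, exponent 2
by default, i.e. a semi-ellipsoid) attached to a planar rigid chest wall at
z = 0, with an ellipsoidal contrast-enhancing tumor kept at least 2 mm
inside the breast surface, and two skin fiducials on the sternal midline:
the upper at the suprasternal notch, the lower 100 mm below (the separation
is constrained to 90–110 mm). Default tissue parameters: breast E = 1 kPa,
tumor 10× stiffer (exposed as `tumor_stiffness_ratio`, since lesion
stiffness relative to gland is patient-specific), ν = 0.45
(near-incompressible but numerically stable with linear tetrahedra),
ρ = 1000 kg/m³.

The MRI emulator rasterises the posed geometry into two co-registered
greyscale channels on one grid — anatomy (breast 200, background 50) and
contrast (tumor 250, background 50) — with additive Gaussian intensity
noise (default sd 5). The scanner emulator samples the visible skin and
the surrounding torso plane uniformly by area and perturbs points along
surface normals with Gaussian noise of sd 0.25 mm, the midpoint of the
0.1–0.4 mm accuracy band of handheld structured-light scanners; the two
fiducials are appended as ideal labelled points (blob detection on real
scans is out of scope).

The training-cohort generator samples breast semi-axes a, b ∈ [42, 58] mm,
c ∈ [42, 65] mm, tumor radius 7–12 mm (aspect 0.8–1.0) at a random interior
position, and breast E ∈ [0.7, 1.5] kPa — a screening-population-like
spread of size, protrusion, lesion geometry and soft-tissue stiffness.
Stiffness is *not* an input to the surrogate; it is observable only through
how far the breast hangs in the prone scan, which is exactly the
information a real system would have.

What the phantoms do **not** emulate: internal fibroglandular texture and
its intensity heterogeneity, Cooper's ligaments, skin as a distinct
stiffer membrane, multi-focal disease, DICOM acquisition artifacts, and
arm-position effects beyond gravity. Passing tests therefore demonstrate
that the pipeline's geometry, mechanics and learning machinery are
self-consistent under realistic magnitudes — not that its accuracy numbers
transfer to patients.

## Segmentation

Threshold segmentation (closed band [low, high]) with Otsu's method as the
default threshold choice, largest-26-connected-component cleanup (ties
broken by the component seen first in C raster order), and surface
extraction by marching cubes on the zero-padded binary field after one
Gaussian pass (σ = 0.5 voxel) to suppress staircase artifacts. Extracted
surfaces are watertight and outward-oriented; both MRI channels share one
grid, so the tumor mask is directly valid in the breast mesh frame.

## Image fusion

The SS scan is the fixed reference. A rigid motion is built in three
stages from the two fiducials: (i) translate the lower fiducials onto each
other; (ii) apply the minimal rotation overlapping the two fiducial lines;
(iii) resolve the remaining degree of freedom — the spin about the common
fiducial axis — by minimising the RMS nearest-neighbour distance between
torso points (coarse 5° sweep, then bounded Brent refinement to 10⁻¹²
rad). The spin is taken about the fiducial axis rather than a gravity-z
axis: once the fiducial lines overlap, that axis is the only rotation that
preserves the overlap. Breast points are excluded from stage-(iii) scoring
by default because the breast deforms between poses while the torso is
nearly rigid; a config switch (`scoring_labels`) restores all-point
scoring. Fusion applies one rigid transform to both MRI meshes, so the
tumor's pose relative to the breast is preserved exactly; all deformable
reposing is the mechanics module's job. The anatomical `LocalFrame`
(origin at the lower tablet, z along gravity, y towards the upper tablet)
is provided for reporting in the surgeon's frame of reference.

## Gravity mechanics

The breast is a compressible neo-Hookean solid,

    W(F) = μ/2 (I₁ − 3) − μ ln J + λ/2 (ln J)²,

discretised with linear tetrahedra in a total-Lagrangian setting and
loaded by its own weight with chest-wall nodes clamped. Newton iterations
with an analytic consistent tangent (verified against finite differences)
run inside incremental loading (default 5 steps); convergence is declared
at a residual below 10⁻⁶ of the external force norm. A backtracking line
search guards against element inversion; on divergence the solve retries
with the load split into twice as many increments (up to 3 doublings).

Tetrahedralization: scipy Delaunay over interior grid points (pitch
`max_edge`, deterministic jitter to break co-spherical degeneracy) plus
cluster-medoid-decimated surface points, keeping tets whose centroid lies
inside the surface. Chest-wall-plane vertices are decimated separately so
the clamped ring survives coarse pitches; tumor-surface points are added
(finer cell, 0.3·pitch) so the lesion is always resolved; degenerate
slivers are dropped and only the largest face-connected tet component is
kept — islands hinged at a single node or edge would make the stiffness
matrix singular. Nodes within 0.5 mm of the wall plane are clamped (at
least 3 required).

**Wall contact.** Supine loading presses the breast against the chest
wall; without contact the tissue folds through the wall plane around the
clamped rim and elements invert. The solver therefore supports a
frictionless quadratic-penalty contact with the wall plane
(`contact_plane=0.0`, enabled on all breast paths, off by default so
analytic benchmarks are unaffected). The penalty stiffness is 50× the
local element stiffness scale, giving sub-0.3 mm penetration at tissue
loads.

**Stress-free inverse.** Reposing from prone to SS is only meaningful from
the unloaded configuration, which is never observed. It is recovered by
Sellier fixed-point iteration: starting from the observed geometry, update
X ← X − (forward(X) − observed). Where the update would invert a tet, the
step is halved *locally* — on that tet's one-ring neighbourhood only, with
global halving as a fallback — so one poorly shaped element cannot stall
the whole iteration. Defaults: tolerance 0.5 mm (0.1 mm in the acceptance
check), max 25 iterations (the pipeline allows 40, since meshes derived
from voxel segmentations carry worse-shaped elements than analytic ones
and converge more slowly); on the default phantom the loop converges in
~6 iterations with a monotone discrepancy trace. `repose` then applies
the new pose's gravity to the recovered unloaded mesh.

Tumor dislocation is the volume-weighted centroid of the tumor-labelled
tets in the target pose minus the source pose. For export, the watertight
marching-cubes surfaces are warped through the FE displacement field by
barycentric interpolation (nearest-candidate containing tet; marginal
exterior points are linearly extrapolated), which preserves watertightness
for printing.

Known limitations, mirrored from the modelling choices: no distinct skin
membrane, no viscoelasticity, isotropic homogeneous regions, linear
tetrahedra (stiff under near-incompressibility — ν defaults to 0.45, and
the ν = 0.495 volume-conservation check passes at <1.5% volume change),
and contact only with the wall plane.

## Deformation surrogate

Per-patient FE is too slow for clinical turnaround, so a feed-forward
network learns the prone→SS map from an FE-simulated cohort. Features are
K = 64 skin landmarks in the source pose plus both gravity unit vectors
(3K + 6 inputs). Landmarks are selected by farthest-point sampling seeded
at the breast apex and then ordered canonically — binned into 22.5° polar
bands about the breast axis and sorted by azimuth within each band — so
landmark *i* refers to roughly the same anatomical region on every
subject; without that canonical ordering the regression targets are
effectively scrambled across subjects and held-out accuracy collapses.
The network predicts landmark *displacements* and the tumor-centroid
*dislocation* vector (3K + 3 outputs); absolute target positions are
recovered by adding back the source landmarks, and the absolute tumor
centroid by adding the dislocation to the (MRI-known) source centroid.
Displacement targets vanish identically when source and target pose agree,
which is the correct degenerate limit.

Architecture and training: 3 hidden layers × 128 ReLU units, Adam with
minibatch 8 and learning rate 10⁻³, strong L2 (α = 0.1, appropriate to a
48-subject training set), 500 epochs, 80/20 train/validation split, inputs
and outputs standardised by training-set statistics (stored on the model);
the squared-error objective is the RMSE criterion up to a monotone
transform. Everything is deterministic under a fixed seed. "Accuracy" is
defined as the fraction of points within δ = 5 mm of their FE ground-truth
positions — a surgical-margin-scale tolerance; δ is configurable.

A structural limit worth stating plainly: the features observe only the
skin, but the tumor's dislocation also depends on its (unobserved) depth
and position inside the breast. The surrogate therefore predicts the
tumor centroid about as accurately as it predicts skin points (~2 mm
median at the 60-subject cohort size) — not better — and that conditional
error floor persists even if the source tumor position is added to the
inputs. Skin-point accuracy is the meaningful headline metric; the tumor
prediction inherits an irreducible uncertainty of the order of the
landmark error.

## Lesion detection

Within a region-of-interest mask (normally the segmented breast, which is
what suppresses spine/rib-cage false positives), each voxel's intensity is
scored as a robust z-score against the ROI median and MAD (×1.4826) and
mapped through the standard-normal CDF: a probability-of-higher-density in
[0, 1], exactly 0 outside the ROI and invariant to affine intensity
rescaling. A zero MAD (constant ROI) falls back to a configured floor with
a warning, scoring the whole ROI at exactly 0.5. Candidates are the
connected components at probability ≥ 0.5. Because the score is
median-centred, about half of any noisy ROI clears 0.5 by chance and that
speckle percolates; a morphological opening (two 6-connected
erosion/dilation passes, config-exposed) removes it — isolated above-median
voxels cannot survive two erosions (survival probability 0.5²⁵ per site)
while solid dense regions a few voxels across do — before a minimum-size
filter (10 voxels) keeps each surviving component.

## Pipeline and reproducibility

`run_pipeline` chains phantom → prone/SS posing → MRI voxelization →
segmentation → lesion detection → fiducial fusion (against an SS scan
expressed in a seeded scanner frame) → stress-free inverse → SS repose →
FE vs. surrogate tumor dislocation → STL export (binary STL per solid plus
a combined multi-solid ASCII scene, tumor as a separate solid so slicers
can highlight it; watertightness and tumor-inside-breast are enforced).
Every run writes a `report.json` (stage numbers), a `manifest.json`
(config hash, seed, per-stage checksums) and a separate `timings.json`;
identical config + seed reproduce manifest and report byte-for-byte. The
CLI (`mammoplan phantom|segment|fuse|simulate|train|predict|detect|export|run`)
is a thin wrapper over the library.

Problem sizes used by the test suite and the acceptance script — chosen as
the coarse end of mesh-converged behaviour: FE pitch 9 mm (~800 nodes,
~4000 tets per subject; halving the pitch changes the tumor-dislocation
magnitude by <10%), 60-subject cohorts for surrogate evaluation, 2–3 mm
voxel grids. The default phantom's prone→SS tumor dislocation is ~8–9 mm,
in the clinically reported range for soft breasts.
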