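# Methods

This note records the models implemented in `mousect`, the assumptions they
make, the parameters that matter, and the choices taken where the design was
genuinely open. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Acquisition model

World frame: right-handed, origin at the isocenter, `z` along the animal
(craniocaudal) axis; the gantry rotates counter-clockwise in the x–y plane,
angle measured from `+x`. The scan is full-rotation step-and-shoot with
equidistant angles. Scanner-scale defaults are a source–isocenter distance
of 117.578 mm, source–detector distance of 297.459 mm (magnification
≈ 2.53) and 1440 projections of 1944 × 1536 pixels. The physical detector
pixel pitch of the scanner is not public; the default (0.167 mm) is chosen
so the detector spans a multi-mouse bed field of view at that magnification
and is always explicit in the geometry. All desk-scale work uses
`desk_geometry()` — 288 projections of 196 × 116 pixels at 0.87 mm pitch —
which covers the packaged four-mouse bed (in-plane FOV radius ≈ 31.5 mm)
with margin.

The detector/beam model maps line integrals `p` to intensities
`I = I₀ · exp(−(c₀ + c₁p + c₂p²))`. The default coefficients (0, 1, 0) give
monochromatic Beer–Lambert; the quadratic term is a configurable stand-in
for beam-hardening and detector-response effects, not a reproduction of any
vendor calibration. It is a strict bijection on `p ≥ 0` whenever `c₁ > 0`
and `c₂ ≥ 0`, and the exact inverse is used for the log transform.
Intensities that are non-positive after noise are clamped at `10⁻⁹·I₀` with
a logged warning.

HU calibration is the affine map `HU = 1000·(µ − µ_w)/µ_w` with
`µ_w = 0.02 mm⁻¹` by default (an effective value for a ~55 kV spectrum),
configurable wherever a conversion happens.

## Projector pair

The forward model integrates the attenuation volume along each
source-to-pixel ray by trilinear interpolation at a fixed step of half the
voxel size; each ray's entry/exit interval is clipped against the volume
bounding box and subdivided into equal steps no longer than that, so the
operator is linear in the volume and exactly scale-equivariant. The
backprojector replays the identical rays, sample positions and trilinear
weights with gather replaced by scatter — it is the algebraic transpose of
the forward operator by construction, and the inner-product identity
`⟨Ax, y⟩ = ⟨x, Aᵀy⟩` holds to rounding error (the tests assert ≤ 10⁻⁴
relative; measured errors are at machine precision). Both kernels are
numba-compiled.

A consequence of fixed-step quadrature is that projections of a voxelized
axisymmetric phantom are *exactly* equal only at gantry angles related by
the symmetry of the voxel lattice (90° steps for a square grid); at
arbitrary angle pairs they agree only to the quadrature order. The
rotational-invariance property is therefore asserted at 90° multiples.

## Reconstruction

The image minimizes `Σ_kept w·(Ax − b)²` via linear conjugate gradient on
the normal equations `AᵀWA x = AᵀWb` with implicit operators, no
preconditioner and no regularization or nonnegativity constraint; smoothing
is handled entirely in preprocessing (Gaussian σ = 1.34 px, then mean
pooling — mean rather than sum so the frames stay in the intensity domain
for the weight model; trailing rows/columns are cropped with a notice when
the dims are not divisible by the bin factor). Weights are `w = I/I₀`
normalized to max 1 — the standard Poisson-like surrogate, since the
variance of `−ln(I/I₀)` is ≈ 1/I for Poisson counts; intensities are
floored at `10⁻⁶·I₀` before weighting. Initialization is zeros; iteration
count is fixed (default 30) with an optional relative-gradient stopping
tolerance. Masked-out projections are omitted from the cost — never
interpolated or substituted — which is what makes per-mouse rejection masks
with arbitrary missing angles possible.

The cost trace is maintained through the exact CG identity
`C_{k+1} = C_k − α_k·r_kᵀr_k`, so it is monotonically nonincreasing without
extra projection passes; correctness of the solver is anchored by a
materialized small system (60 × 27) whose CG solution is compared against
the direct weighted least-squares solve.

## Intrinsic gating

Per mouse of interest: coarse preview reconstruction from all raw data →
sphere signal curve → baseline subtraction → median high-pass → rank
selection.

* The ROI sphere is an explicit input (center at the MOI diaphragm,
  diameter in mm); there is no automatic diaphragm detection.
* The raw curve is computed on the binned intensity-domain frames (faster;
  whether the original computed it before or after binning is unknown). A
  pixel belongs to the projected sphere when its source ray passes within
  the sphere radius of the center; the curve errors out, naming the angle,
  if the projected sphere is empty or clipped by the detector border.
* The baseline is the same curve computed on the forward-projected coarse
  reconstruction converted back to the intensity domain; subtracting it
  removes the variation that merely reflects gantry rotation.
* The high-pass subtracts a sliding median, window `2·4 + 1 = 9` samples,
  reflected boundaries. A gasp shorter than half the window passes the
  filter essentially unattenuated, which is why the packaged phantom uses
  4-projection gasps.
* `select_rejections` discards exactly `k = round(RF·n)` (half-up)
  projections by rank on the score; ties break toward the lower projection
  index, making the rejection sets nested across increasing RF. The
  polarity of the motion deflection depends on the direction of diaphragm
  excursion and on the curve domain, so it is a config enum
  `{lowest, highest, absolute}`. The generic default is `lowest`; for the
  packaged phantom the physical polarity is `highest` (a caudal gasp pulls
  lung into the ROI, raising transmission), and `absolute` is the robust
  fallback when the sign is unknown.
* The coarse preview defaults to 4× coarser voxels and 5 CG iterations with
  unit weights. That ratio is tuned to a production-scale 80 µm grid; at
  the desk scale (1 mm reconstruction voxels, 8 mm-wide mice) the packaged
  study uses a 2× / 14-iteration preview instead, because 4 mm preview
  voxels cannot follow the anatomy.

## The synthetic phantom

What it emulates: four anesthetized, contrast-enhanced, tumor-bearing mice
side by side in a bed; per mouse a soft-tissue ellipsoid body
(semi-axes 4 × 4 × 12 mm, 40 HU), a hypodense lung compartment (−500 HU)
cranial of the diaphragm, a contrast-enhanced liver (400 HU) caudal of it,
and two 3 mm hypodense tumors (60 HU) inside the liver; a homogeneous bed
cylinder (−200 HU) under the animals. Tissue HU values are invented,
config-overridable defaults of the right order for ExiTron-enhanced liver
imaging, not measurements. Mice sit 16 mm apart (centers at
x = ±8, ±24 mm), which makes neighbor silhouettes overlap at roughly a
third of the gantry angles and distant pairs progressively less.

Breathing: a gasp is a raised-cosine (sin²) pulse of the diaphragm's caudal
displacement, duration 4 projections, mean period 18 projections, Gaussian
timing jitter (σ = 1 projection), amplitude 2 mm, independent timing per
mouse. Only the lung/liver interface, the liver span and the tumors
translate; the body outline is static and there is no tissue compression —
sufficient to produce the edge-hypodensity artifact, but not a
biomechanical model. With these kinematics the fraction of projections a
rater would discard for an outer mouse (own gasps plus overlapped
neighbors' gasps) comes out near 0.2, which is the regime the method
targets.

Rater labels: the grade of projection `t` for MOI `m` is
`round(10 · max_j rel_j(t) · w_j)` where `rel_j` is mouse `j`'s displacement
relative to its own amplitude, `w_j = 1` for the MOI itself and the graded
silhouette-overlap fraction for other mice (transaxial overlap length of
the cone-beam-projected bounding cylinders divided by the narrower
silhouette width, zero if the axial extents do not intersect). This mirrors
the rater protocol of grading full overlapped motion 10, devaluing weaker
motion and slight overlaps proportionally, and ignoring motion without
overlap. Binary overlap (`overlap_matrix`) is the thresholded version used
by the rejection-mode bookkeeping. The graded rule is one consistent
formalization of a human judgment, not a claim about any specific rater.

Noise: Poisson sampling of the detector counts at a photon budget of
I₀ = 4000 per full-resolution pixel, seeded. There is no scatter, no
detector blur, no focal-spot size, no spectral (beam-hardening) physics in
the simulation.

Simulation uses a 0.5 mm voxel grid; reconstruction uses 1.0 mm voxels on
the same physical box, so forward and inverse models are deliberately
discretized differently. A consequence worth knowing: the voxelization
mismatch puts an artifact floor of a few tens of HU into the reconstruction
that acts as structured "noise" in the bed region and converges over CG
iterations — which is why gated-vs-ungated CNR comparisons are made between
equally converged (30-iteration) reconstructions, and why the noise ROI is
large enough (≈ 90 voxels) for a stable standard-deviation estimate.

What passing tests therefore do *not* show: performance under real detector
physics (scatter, afterglow, beam hardening), real anatomy (deformable
organs, cardiac motion, graded rater idiosyncrasies), or production problem
sizes.

## Evaluation metrics

* Line profiles are sampled by trilinear interpolation at half-voxel
  spacing; the slope is ordinary least squares over an explicit fit segment
  (the original study chose segments manually per mouse, so segment
  endpoints are inputs). The packaged profile runs craniocaudally through
  the MOI liver across the cranial edge (7.2 mm, fit over 0.5–5.5 mm).
* ROI means average voxels whose centers lie inside the sphere; a sphere
  containing no centers is an error.
* CNR = (mean liver − mean tumor) / sample SD of a homogeneous bed sphere.
  Tumor segmentations are inputs (the packaged ones are the true tumor
  spheres).
* Agreement counts per-projection binary keep/discard matches between the
  algorithmic mask and thresholded rater labels (discard at grade ≥ 3),
  reported as percent with confusion counts and Cohen's kappa for context.
* The three rejection modes: *single-mouse* discards on the MOI's own
  grades only; *overlap-based* additionally on overlap-weighted grades of
  other mice; *additive* on any mouse's grades regardless of overlap. By
  construction the rejection sets are nested, so the used fractions are
  ordered. The relative single-vs-overlap difference is reported with the
  overlap-based fraction as denominator.
* `rf_sweep` computes the motion score once and re-ranks it per RF, then
  reconstructs and evaluates each RF; the rejection sets are nested across
  the sweep.

## Problem sizes

The test suite and the acceptance script run everything at desk scale: the
packaged 288-angle four-mouse scan (full-resolution detector 196 × 116,
binned 2× to 98 × 58), 60 × 16 × 26 reconstructions at 1 mm voxels with 30
CG iterations for quality comparisons, a 64³ / 180-angle noiseless phantom
for self-consistency, and an RF sweep over {0, 0.05, …, 0.35}. Full
acquisition-scale numbers (1440 × 1944 × 1536, 80 µm voxels) are retained
as configuration presets only.

## Known limitations

* The adjoint is matched to the trilinear-sampling forward model rather
  than to an exact footprint model; both inherit half-voxel quadrature
  error.
* The beam/detector model is a polynomial stand-in; no vendor response
  curve is reproduced.
* Bounding-cylinder silhouettes slightly overestimate ellipsoid bodies, so
  graded overlap fractions near tangency are approximate.
* ROI placement for gating is manual by design; automatic diaphragm
  detection is out of scope.
* Phase binning into multiple respiratory phases (4-D reconstruction) and
  motion-compensated reconstruction are not implemented.
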