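# Methods

## The model and its assumptions

`vesselfield` treats per-subject 3D vessel reconstruction as fitting a
continuous occupancy field to two cone-beam projections. The field is the
composition of a multiresolution hash encoder (trainable feature tables
Θ) and a residual MLP (weights Φ); the only supervision is the
reprojection mean-squared error against the two input detector images.
The key assumptions are:

- the two views' acquisition geometry (DSD, DSO, primary/secondary gantry
  angles, detector pitch) is known exactly and shares one isocenter with
  the reconstruction grid;
- the imaged object is a binary vessel tree of uniform attenuation 1, so a
  detector pixel's value is the vessel chord length (in mm) along its ray
  — the log-domain Beer–Lambert exponent, not the exponentiated intensity
  (the exponentiated map `exp(-p)` is available as a post-map for users
  whose inputs are raw intensities);
- the subject is static across the two views (no cardiac/respiratory
  motion between acquisitions).

## Coordinate model

Voxel indices are 1-based at the API boundary and mapped to physical
coordinates centered on the isocenter, `x' = (i-1)s - (ns - s)/2`, so the
voxel-center grid is symmetric under negation and the cone-beam isocenter
coincides with the volume center. The offset is read in its symmetric form
deliberately: the asymmetric alternative `ns - s/2` would place the volume
almost entirely on one side of the rotation axis, which is physically
implausible for C-arm imaging.

Angle convention: the primary angle (LAO/RAO) rotates the source–detector
arm about the patient head–foot axis (+z), the secondary angle
(cranial/caudal) about the patient left–right axis (+x), composed primary
first. At zero angles the source sits at (0, −DSO, 0). This matches
standard C-arm usage; no consensus convention exists, so the choice is
recorded here and serialized with every geometry sidecar.

Clinical view pairs are sampled uniformly and independently inside
per-artery parameter ranges (RCA: DSD 970–1010 mm / 1050–1070 mm,
DSO 745–785 mm with plane 2 within ±3 mm, primary 18°–42° then −8°–8°,
secondary −8°–8° then 18°–42°; LAD: DSD 1030–1090 mm with plane 2 +70 mm,
DSO 740–760 mm with plane 2 +3 mm, primary −8°–8° then −47°–−23°,
secondary 18°–42° then 21°–45°; detector 512² at 0.2769–0.2789 mm pitch).
The +3 mm plane-2 DSO offset for LAD is applied as printed (signed, not a
magnitude). The orthogonal-view variant keeps the base view and adds a
second view whose beam axis is horizontal and exactly perpendicular to the
base's.

## Encoder

Defaults follow the clinical profile: L = 16 levels, T = 2¹⁹ table rows,
F = 2 features, N_min = 16, growth factor b = 2. Levels with
(N_l + 1)³ ≤ T index vertices one-to-one (at T = 2¹⁹ that is every level
with N_l ≤ 79); finer levels use the spatial hash with primes
(1, 2654435761, 805459861), products in unsigned 32-bit wraparound
arithmetic, XOR-combined, reduced mod T by bitwise AND. The hash is applied
to the integer lattice coordinates of each level's grid, not to continuous
coordinates. Collisions are left unresolved at lookup; gradient-based
optimization weights the competing updates by their loss sensitivity, which
in practice favors voxels on the vessel. Tables initialize uniformly in
[−10⁻⁴, 10⁻⁴] from the run seed. Note that with b = 2 the finest level of
the default configuration (N_15 = 524288) far exceeds the 128-voxel grid;
the configuration object exposes L and b so users can cap the finest
resolution, but the defaults are kept as stated.

Per-level rescaling maps the physical volume extent onto [0, N_l]³; points
exactly on the upper boundary are clamped into the last cell. For repeated
evaluation on the fixed voxel grid, each level's gather-and-interpolate is
precomputed once as a sparse stencil matrix S_l (8 weights per voxel), so
encoding is `S_l @ table_l` and the exact table gradient is
`S_lᵀ @ d_features` — no approximation is involved; the pointwise encoder
and the cached path agree to machine precision (tested).

## Occupancy MLP

Eight weight layers (the eighth produces the scalar), hidden width 256,
LeakyReLU (negative slope 0.01) on all hidden layers, sigmoid on the
output. "Residual learning in the middle layer" is realized as a skip that
concatenates the encoded features onto the activations entering layer 5
(layer `n/2 + 1` in general): a plain addition is impossible without a
projection because the widths differ (L·F = 32 vs 256), and concatenation
preserves the original feature information unchanged. Weights initialize
with the fan-in uniform scheme from the run seed. The backward pass is
written analytically and validated against central finite differences.

## Projector

Ray-driven line integration: for every detector pixel, the ray from the
source through the pixel center is sampled at fixed step Δt (default half
the smallest voxel spacing) with trilinear interpolation over the
voxel-center hull and zero outside; the pixel value is the sample sum × Δt.
Because the sampling stencil is fixed by the geometry, the whole operator
is materialized once as a sparse matrix A: forward projection is `A @ v`,
the adjoint is exactly `Aᵀ`, the operator is linear in the volume, and the
gradient of any projection-domain loss with respect to the voxels is one
adjoint application. The dot-product identity ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ holds to
rounding error by construction and is tested against a dense-matrix oracle
built by projecting unit basis volumes.

Discretization: trilinear interpolation over voxel centers truncates half
a voxel at each face, so a uniform cube of extent E = n·s integrates to
(n−1)·s on an axis-aligned ray; at 128 voxels this is a 0.8% deficit
(tested < 1%), at coarser grids proportionally more. The midpoint sampling
overshoots by at most Δt/2 at the exit face. Halving Δt changes the
integral by well under 1% (tested).

## Optimization and post-processing

One iteration renders the full voxel grid through encoder + MLP, projects
it with every view's sparse operator, accumulates the mean-squared
residual over all views and pixels, backpropagates analytically, and takes
one Adam step (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) on Θ and Φ jointly.
The loss normalizes by the total pixel count over all views; any constant
rescaling of the loss is absorbed by Adam's per-parameter step
normalization and only shifts the effective learning rate.
The clinical profile runs 5000 iterations at learning rate 10⁻⁴. The loss
is recorded every iteration; when ground truth is supplied, the six
metrics of the intermediate cleaned reconstruction are recorded every
`log_every` (default 100) iterations. A non-finite loss aborts with a
diagnostic rather than continuing silently.

Binarization is strictly-greater-than 0.5 (exact ties map to background —
the occupancy is a sigmoid output, so exact 0.5 occurs only for a zeroed
network). Cleaning removes 26-connected components under 25 voxels;
26-connectivity is the standard choice for thin tubular structures, where
diagonal voxel contacts are common. Cleaning is idempotent and never adds
voxels.

The training path runs in float32 (the sparse operators and dense layers
are memory-bandwidth-bound; float64 roughly doubles the cost without
changing any tested behavior); gradient-check tests run the identical code
path in float64.

## Profiles and problem sizes

Two named profiles:

- **paper** (clinical fidelity): 128³ voxels at 0.703125 mm (90 mm field
  of view), 512² detector, the full encoder (L = 16, T = 2¹⁹) and MLP
  (8 × 256), 5000 iterations at lr 10⁻⁴. Intended for long runs; building
  the 512²-ray sparse operator at this scale is memory-hungry and is the
  known scalability limit of the materialized-operator design.
- **test** (desk scale): 32³ voxels at the same 0.703125 mm pitch — a
  22.5 mm coronary subvolume rather than a coarsened whole heart, so that
  clinically realistic vessel radii (trunk 1.5–2.5 mm, leaves ≥ 0.65 mm)
  stay multi-voxel structures and recovery scores are meaningful — 64²
  detector at 1.0 mm pitch, reduced encoder (L = 8, T = 2¹⁴, N_min = 4),
  4 × 64 MLP, 800 iterations at lr 10⁻³ (the usual Adam regime for small
  networks; 10⁻⁴ with a 64-wide network converges far more slowly than
  the full-width model it was chosen for). One two-view fit takes about
  100 s on one CPU core; recovery Dice plateaus from roughly iteration
  500, so the test suite and the acceptance script run 600-iteration fits.

## The phantom generator

`simulate_case` stands in for segmented CCTA coronary trees: a trunk grown
as a jittered cubic-spline curve spanning the volume (RCA-like trees sweep
a C-shaped transverse arc; LAD-like trees run head–foot), 2–6 side
branches leaving the trunk at random stations with child radii 0.6–0.85 of
the parent, radii tapering monotonically to leaves ≥ 0.65 mm (floor chosen
so that thin tips remain 26-connected after voxel-center rasterization at
0.7 mm pitch). Trees are rasterized as unions of linearly tapered capsules
by voxel-center membership with no antialiasing — matching the hard-binary
character of segmented clinical volumes — and projected with uniform
attenuation 1. Everything is deterministic under the case seed.

What the phantoms do **not** emulate: real coronary branching statistics
and tortuosity, stenoses and aneurysms, partial-volume effects at vessel
boundaries, background organs/contrast, detector noise, or motion. Passing
recovery tests therefore demonstrate that the optimization pipeline can
invert its own forward model on vessel-like topology at desk scale — not
clinical-grade performance on patient data.

## Metrics

- Dice and IoU over foreground voxels; both conventions return 1 when both
  volumes are empty so trivially perfect cases score perfect.
- clDice from 3D medial-axis thinning (Lee's method via scikit-image).
  Degenerate blobs that thinning erases entirely keep themselves as their
  own skeleton, so identical volumes always score 1; if exactly one volume
  is empty the score is 0.
- Chamfer ℓ₂ uses all foreground voxel centers in physical mm (symmetric
  mean of nearest-neighbor distances, KD-tree accelerated); with one empty
  volume it is undefined and reported as NaN. At 128³ scale a surface-only
  point cloud is the tractable alternative; at test scale full clouds are
  used.
- reError is the relative absolute volumetric error Σ|P−G| / ΣG, i.e.
  (FP+FN)/|G| for binary volumes — the definition consistent with
  jointly reported Dice/IoU/reError triples; reMSE is the mean squared
  voxel difference over the whole grid.

## Known limitations

- The materialized sparse operator trades memory for exactness and speed;
  at 512² detectors × 128³ volumes it reaches tens of gigabytes of
  stencil entries and a streaming (matrix-free) projector would be needed.
- Occupancy can fit the projections well while hovering below the 0.5
  threshold early in optimization (reconstructions are empty for the
  first few hundred iterations, then snap in); clinical-angle view pairs,
  which share more redundant information than orthogonal pairs, recover
  less reliably and with higher seed-to-seed variance — the same ordering
  the full-scale method exhibits.
- The exact acquisition geometry is assumed known; no pose refinement is
  performed.
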