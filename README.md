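# vesselfield

Self-supervised 3D coronary artery tree reconstruction from **two** 2D
cone-beam angiographic projections, using a neural implicit occupancy field.

During cardiac catheterization, usually only two X-ray projections of the
contrast-filled coronary tree are acquired, which makes the 3D vessel
geometry hard to judge from the 2D planes. `vesselfield` reconstructs the 3D
tree from exactly those two views, **per subject**: no 3D ground truth, no
training corpus — the network is fitted from scratch to each case. It is
aimed at researchers in cardiovascular image analysis who want a
reproducible, CPU-runnable reference implementation with a built-in phantom
generator and evaluation suite.

## Method

The vessel tree inside a centered voxel grid is represented as a continuous
occupancy field. For a voxel with 1-based index $(x, y, z)$, the centered
physical coordinate is

$$x'_i = (x_i - 1)\,s_i - \tfrac{n_i s_i - s_i}{2},$$

with $n_i$ voxels of spacing $s_i$ per axis, so the grid is symmetric about
the isocenter. Each coordinate is featurized by a **multiresolution hash
encoder** $H_v = \mathrm{enc}(x'; \Theta)$: at $L$ levels of resolution
$N_\ell = N_{\min} b^\ell$ the enclosing grid cell's 8 vertices are looked
up in a learnable table of $T$ rows × $F$ features (one-to-one for coarse
levels, via the spatial hash
$h(v) = (\oplus_i\, v_i \pi_i) \bmod T$ with primes
$\pi = (1,\,2654435761,\,805459861)$ for fine levels), trilinearly
interpolated and concatenated into a length-$LF$ vector. A **residual MLP**
$\mu = m(H_v; \Phi)$ (8 fully connected layers, width 256, LeakyReLU, a
mid-network skip re-injecting $H_v$, sigmoid output) maps features to
occupancy $\mu \in (0, 1)$.

A **differentiable cone-beam projector** renders the occupancy volume into
detector-plane line integrals for each acquisition geometry (DSD, DSO,
primary/secondary gantry angles). The parameters $(\Theta, \Phi)$ are fitted
with Adam by minimizing the reprojection error

$$\mathcal{L}(\Theta, \Phi) = \frac{1}{N \cdot I}\sum_n^N \sum_i^I
\left(P_{ni} - G_{ni}\right)^2,$$

over the $N{=}2$ simulated projections $P$ against the input projections
$G$ ($I$ = detector pixels per view). The final volume is binarized at 0.5
and 26-connected components below 25 voxels are removed.

Evaluation uses six metrics: clDice (centerline-Dice topology score), Dice,
IoU, reError ($\sum|P-G| / \sum G$), symmetric Chamfer $\ell_2$ distance in
mm, and reMSE (mean squared voxel error).

In this implementation the projector and the per-level encoder stencils are
materialized as sparse matrices over the fixed voxel grid, so forward
projection and its adjoint are exact transposes of each other and all
parameter gradients are analytic — everything runs on plain
numpy/scipy, one CPU core is enough for desk-scale problems.

## Worked example

Fit a 32³ synthetic coronary phantom (22.5 mm field of view at clinical
voxel pitch) from two orthogonal views and score it
(`examples/reconstruct_two_views.py`, a few minutes on one core):

```
initial projection MSE: 22.5369
final projection MSE:   0.001241 (5.51e-05 of initial)
Dice     0.848   (overlap with ground truth)
clDice   0.819   (centerline topology preservation)
IoU      0.736
reError  0.311   ((FP+FN)/|GT| volumetric error)
CD_l2    0.136 mm (symmetric surface-cloud distance)
reMSE    6.35e-03 (mean squared voxel difference)
```

The projection error drops by more than four orders of magnitude and the
binarized reconstruction overlaps the hidden ground-truth tree at Dice 0.85;
the 0.14 mm Chamfer distance is well below the 0.70 mm voxel pitch. Other
examples: `simulate_phantom.py` (what a synthetic case contains),
`projector_basics.py` (adjoint identity, analytic cube integral),
`orthogonal_vs_clinical_views.py` (view-geometry effect on recovery).

A thin CLI wraps the same library calls:

```
vesselfield run --style lad --seed 1 --scale test --views orthogonal --out run1/
vesselfield evaluate --pred run1/reconstruction.nii.gz --gt run1/ground_truth.nii.gz --out report.csv
```

Volumes are NIfTI, projections float32 multi-page TIFF with a JSON geometry
sidecar, configuration YAML; every run writes a manifest with its seed and
config hash.

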