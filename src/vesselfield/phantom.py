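"""Seeded synthetic coronary-tree phantoms.

Generates vessel trees as smooth random centerline curves with tapering
radii, rasterizes them as unions of capsules (voxel centers within radius of
a centerline segment) into binary volumes, and simulates the two-view
cone-beam acquisition with uniform vessel attenuation 1.  The trees emulate
the character of binary segmented coronary arteries (a single connected,
tapering, branching tube) without claiming hemodynamic realism; they exist
so the whole reconstruction pipeline can be exercised and validated without
any external imaging data.

Styles: "RCA"-like trees curve around the volume (the right coronary artery
hugs the atrioventricular groove); "LAD"-like trees run roughly head-foot
with diagonal side branches.  Both are statistical caricatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .geometry import (
    ConeBeamGeometry,
    DetectorSpec,
    VolumeSpec,
    orthogonal_pair,
    sample_projection_pair,
)
from .projector import ConeBeamProjector, Projection

__all__ = ["Branch", "VesselTree", "SimulatedCase", "generate_tree", "rasterize", "simulate_case"]


@dataclass
class Branch:
    """A centerline polyline (points in mm) with a per-point radius (mm)."""

    points: np.ndarray  # (n, 3)
    radii: np.ndarray  # (n,)


@dataclass
class VesselTree:
    """Branches plus parent links (-1 for the trunk); tree-structured."""

    branches: list[Branch]
    parents: list[int]
    artery_style: str

    def __post_init__(self) -> None:
        for i, p in enumerate(self.parents):
            if not (-1 <= p < i):
                raise ValueError("parent links must form a forest ordered root-first")


@dataclass
class SimulatedCase:
    """One synthetic subject: ground truth, two projections, provenance."""

    ground_truth: np.ndarray
    vol: VolumeSpec
    projections: list[Projection]
    tree: VesselTree
    seed: int


def _smooth_curve(ctrl: np.ndarray, n_samples: int) -> np.ndarray:
    """Cubic-spline interpolation through control points, arc-parameterized."""
    t = np.linspace(0.0, 1.0, ctrl.shape[0])
    spline = CubicSpline(t, ctrl, axis=0)
    return spline(np.linspace(0.0, 1.0, n_samples))


def generate_tree(
    style: str,
    seed: int,
    vol: VolumeSpec,
    branch_range: tuple[int, int] = (2, 6),
    trunk_radius_range: tuple[float, float] = (1.5, 2.5),
    leaf_radius_range: tuple[float, float] = (0.65, 0.9),
) -> VesselTree:
    """Grow a random coronary-like tree inside the physical volume bounds.

    The trunk spans the volume as a smooth jittered curve; 2-6 side branches
    leave the trunk at random stations, radii taper monotonically from the
    trunk value (~1.5-2.5 mm) toward the leaves (>= 0.5 mm, default floor
    0.65 mm so thin tips stay voxel-connected at clinical voxel pitch).
    Fully reproducible under the seed.
    """
    style = style.upper()
    if style not in ("RCA", "LAD"):
        raise ValueError(f"style must be 'RCA' or 'LAD', got {style!r}")
    rng = np.random.default_rng(seed)
    half = np.asarray(vol.extent) / 2.0
    r_trunk = float(rng.uniform(*trunk_radius_range))
    r_leaf_trunk = float(rng.uniform(*leaf_radius_range))
    margin = r_trunk + max(vol.spacing)
    box = half - margin  # centerlines stay this far inside the boundary

    # trunk: spans the volume along a style-dependent principal axis
    main_axis = 2 if style == "LAD" else 0
    n_ctrl = 5
    stations = np.linspace(-box[main_axis], box[main_axis], n_ctrl)
    ctrl = np.empty((n_ctrl, 3))
    ctrl[:, main_axis] = stations
    for axis in range(3):
        if axis == main_axis:
            continue
        amplitude = 0.45 * box[axis]
        if style == "RCA":
            # C-shaped sweep in the transverse plane
            phase = rng.uniform(0, np.pi)
            ctrl[:, axis] = amplitude * np.sin(
                np.linspace(0, np.pi, n_ctrl) + phase * 0.2
            ) * rng.choice([-1.0, 1.0])
        else:
            ctrl[:, axis] = rng.uniform(-0.3 * box[axis], 0.3 * box[axis], n_ctrl)
        ctrl[:, axis] += rng.normal(0.0, 0.08 * box[axis], n_ctrl)
    n_pts = 80
    trunk_pts = np.clip(_smooth_curve(ctrl, n_pts), -box, box)
    trunk_radii = np.linspace(r_trunk, r_leaf_trunk, n_pts)
    branches = [Branch(trunk_pts, trunk_radii)]
    parents = [-1]

    n_side = int(rng.integers(branch_range[0], branch_range[1] + 1))
    for _ in range(n_side):
        u = float(rng.uniform(0.15, 0.85))
        i_root = int(u * (n_pts - 1))
        root = trunk_pts[i_root]
        r_root = float(trunk_radii[i_root]) * float(rng.uniform(0.6, 0.85))
        tangent = trunk_pts[min(i_root + 1, n_pts - 1)] - trunk_pts[max(i_root - 1, 0)]
        tangent /= np.linalg.norm(tangent) + 1e-12
        # random departure direction, biased away from the trunk tangent
        d = rng.normal(size=3)
        d -= 0.7 * np.dot(d, tangent) * tangent
        d /= np.linalg.norm(d) + 1e-12
        length = float(rng.uniform(0.35, 0.8)) * float(np.min(box))
        n_c = 4
        b_ctrl = root[None, :] + np.outer(np.linspace(0, 1, n_c), d * length)
        jitter = rng.normal(0.0, 0.06 * length, (n_c, 3))
        jitter[0] = 0.0  # the root stays on the parent centerline
        b_ctrl = b_ctrl + jitter
        b_pts = _smooth_curve(b_ctrl, 40)
        b_pts[0] = root
        b_pts = np.clip(b_pts, -box, box)
        b_pts[0] = root
        r_tip = min(r_root, float(rng.uniform(*leaf_radius_range)))
        branches.append(Branch(b_pts, np.linspace(r_root, r_tip, 40)))
        parents.append(0)
    return VesselTree(branches, parents, style)


def rasterize(tree: VesselTree, vol: VolumeSpec) -> np.ndarray:
    """Binary volume: voxel = 1 iff its center lies inside any capsule.

    Each consecutive centerline pair forms a capsule (cylinder with
    spherical caps) whose radius interpolates linearly along the segment;
    membership is evaluated on voxel centers with no antialiasing, matching
    the character of binary segmented angiographic volumes.
    """
    size = np.asarray(vol.size)
    spacing = np.asarray(vol.spacing)
    half = np.asarray(vol.extent) / 2.0
    out = np.zeros(tuple(size), dtype=np.uint8)
    if not tree.branches:
        return out
    origin = -half + spacing / 2.0  # center of voxel (0,0,0)
    for branch in tree.branches:
        pts, radii = branch.points, branch.radii
        for a, b, ra, rb in zip(pts[:-1], pts[1:], radii[:-1], radii[1:]):
            r_max = max(ra, rb)
            lo = np.maximum(
                np.floor((np.minimum(a, b) - r_max - origin) / spacing).astype(int), 0
            )
            hi = np.minimum(
                np.ceil((np.maximum(a, b) + r_max - origin) / spacing).astype(int) + 1,
                size,
            )
            if np.any(lo >= hi):
                continue
            axes = [origin[i] + spacing[i] * np.arange(lo[i], hi[i]) for i in range(3)]
            gx, gy, gz = np.meshgrid(*axes, indexing="ij")
            p = np.stack([gx, gy, gz], axis=-1)
            ab = b - a
            denom = float(np.dot(ab, ab))
            if denom < 1e-18:
                t = np.zeros(p.shape[:-1])
            else:
                t = np.clip(np.einsum("...k,k->...", p - a, ab) / denom, 0.0, 1.0)
            closest = a + t[..., None] * ab
            r_here = ra + (rb - ra) * t
            inside = np.sum((p - closest) ** 2, axis=-1) <= r_here**2
            out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= inside.astype(np.uint8)
    return out


def simulate_case(
    style: str,
    seed: int,
    vol: VolumeSpec | None = None,
    views: str = "clinical",
    detector: DetectorSpec | None = None,
    projector_step: float | None = None,
) -> SimulatedCase:
    """Generate one complete synthetic subject.

    Pipeline: grow a tree, rasterize it, draw the two-view acquisition
    geometry (clinical angle ranges, or the base view plus an orthogonal
    one), and forward-project the binary volume with uniform attenuation 1.

    Default grid: 32 voxels per axis at clinical voxel pitch 0.703125 mm
    (a 22.5 mm coronary subvolume), detector 64 x 64 at 1.0 mm pitch.
    """
    if vol is None:
        vol = VolumeSpec.isotropic(32, 0.703125)
    if detector is None:
        detector = DetectorSpec((64, 64), (1.0, 1.0))
    if views not in ("clinical", "orthogonal"):
        raise ValueError("views must be 'clinical' or 'orthogonal'")
    tree = generate_tree(style, seed, vol)
    gt = rasterize(tree, vol)
    g1, g2 = sample_projection_pair(style, seed, detector=detector)
    if views == "orthogonal":
        g1, g2 = orthogonal_pair(g1)
    projections = []
    for geom in (g1, g2):
        op = ConeBeamProjector(geom, vol, projector_step)
        # uniform attenuation 1 inside the vessel
        projections.append(Projection(op.forward(gt.astype(np.float64)), geom, vol))
    return SimulatedCase(gt, vol, projections, tree, seed)
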