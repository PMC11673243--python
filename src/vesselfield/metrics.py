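"""Six-metric evaluation of a binary reconstruction against ground truth.

Overlap: Dice and IoU over foreground voxels.  Topology: centerline Dice
(clDice) — the harmonic mean of topology precision |skel(P) & G| / |skel(P)|
and topology sensitivity |skel(G) & P| / |skel(G)|, with skeletons from 3D
medial-axis thinning.  Geometry: symmetric Chamfer L2 distance between the
foreground voxel-center point clouds in physical mm.  Error rates: reError
(relative absolute volumetric error, sum |P - G| / sum G; equal to
(FP + FN) / |G| for binary volumes) and reMSE (mean squared voxel
difference, (FP + FN) / total voxels for binary volumes).

The small-component filter of the reconstruction stage is expected to have
been applied to the prediction before evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

__all__ = [
    "MetricsReport",
    "dice",
    "iou",
    "cl_dice",
    "chamfer_l2",
    "re_error",
    "re_mse",
    "evaluate",
    "summarize_reports",
]


@dataclass(frozen=True)
class MetricsReport:
    """One case's six evaluation values."""

    cl_dice: float
    dice: float
    iou: float
    re_error: float
    chamfer_l2: float  # mm; NaN when either volume is empty (undefined)
    re_mse: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _binarize_pair(pred, gt):
    p = np.asarray(pred).astype(bool)
    g = np.asarray(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return p, g


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap 2|P&G| / (|P|+|G|); 1 when both volumes are empty."""
    p, g = _binarize_pair(pred, gt)
    denom = p.sum() + g.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(p, g).sum() / denom


def iou(pred: np.ndarray, gt: np.ndarray) -> float:
    """Intersection over union |P&G| / |P|G|; 1 when both are empty."""
    p, g = _binarize_pair(pred, gt)
    union = np.logical_or(p, g).sum()
    if union == 0:
        return 1.0
    return np.logical_and(p, g).sum() / union


def cl_dice(pred: np.ndarray, gt: np.ndarray, spacing=None) -> float:
    """Centerline Dice: topology-aware overlap via skeleton containment.

    Tprec = |skel(P) & G| / |skel(P)|, Tsens = |skel(G) & P| / |skel(G)|,
    clDice = 2 Tprec Tsens / (Tprec + Tsens).  1 when both volumes are
    empty, 0 when exactly one is empty or a needed skeleton vanishes.
    The ``spacing`` argument is accepted for signature symmetry with the
    distance metrics; thinning operates on the voxel lattice.
    """
    p, g = _binarize_pair(pred, gt)
    if not p.any() and not g.any():
        return 1.0
    if not p.any() or not g.any():
        return 0.0
    skel_p = _skeleton(p)
    skel_g = _skeleton(g)
    tprec = np.logical_and(skel_p, g).sum() / skel_p.sum()
    tsens = np.logical_and(skel_g, p).sum() / skel_g.sum()
    if tprec + tsens == 0:
        return 0.0
    return 2.0 * tprec * tsens / (tprec + tsens)


def _skeleton(mask: np.ndarray) -> np.ndarray:
    """Medial-axis thinning; degenerate blobs that thin away entirely keep
    themselves as their own skeleton."""
    skel = skeletonize(mask).astype(bool)
    return skel if skel.any() else mask


def _foreground_points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    idx = np.argwhere(mask)
    return idx * np.asarray(spacing, dtype=float)


def chamfer_l2(pred: np.ndarray, gt: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric Chamfer L2 distance between foreground voxel centers, mm.

    0.5 * (mean_P min-dist-to-G + mean_G min-dist-to-P), Euclidean norm in
    physical coordinates.  0 when both are empty; NaN (undefined) when
    exactly one is empty.
    """
    p, g = _binarize_pair(pred, gt)
    if not p.any() and not g.any():
        return 0.0
    if not p.any() or not g.any():
        return float("nan")
    pts_p = _foreground_points_mm(p, spacing)
    pts_g = _foreground_points_mm(g, spacing)
    d_pg, _ = cKDTree(pts_g).query(pts_p, k=1)
    d_gp, _ = cKDTree(pts_p).query(pts_g, k=1)
    return 0.5 * (d_pg.mean() + d_gp.mean())


def re_error(pred: np.ndarray, gt: np.ndarray) -> float:
    """Relative absolute volumetric error sum|P-G| / sum G."""
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gt, dtype=float)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    denom = g.sum()
    if denom == 0:
        raise ValueError("reError undefined for empty ground truth")
    return float(np.abs(p - g).sum() / denom)


def re_mse(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean squared voxel difference over the whole grid."""
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gt, dtype=float)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    d = p - g
    return float(np.mean(d * d))


def evaluate(pred: np.ndarray, gt: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> MetricsReport:
    """All six metrics for one (cleaned) binary prediction."""
    return MetricsReport(
        cl_dice=float(cl_dice(pred, gt, spacing)),
        dice=float(dice(pred, gt)),
        iou=float(iou(pred, gt)),
        re_error=float(re_error(pred, gt)),
        chamfer_l2=float(chamfer_l2(pred, gt, spacing)),
        re_mse=float(re_mse(pred, gt)),
    )


def summarize_reports(reports: Sequence[MetricsReport]) -> dict[str, dict[str, float]]:
    """Per-metric mean and standard deviation across cases."""
    out: dict[str, dict[str, float]] = {}
    for f in fields(MetricsReport):
        vals = np.array([getattr(r, f.name) for r in reports], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[f.name] = {
            "mean": float(vals.mean()) if vals.size else float("nan"),
            "std": float(vals.std(ddof=0)) if vals.size else float("nan"),
        }
    return out
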