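"""Self-supervised per-subject reconstruction.

The occupancy field (hash tables Theta + MLP weights Phi) is fitted to a
single subject's two projections by gradient descent on the mean squared
projection error

    L(Theta, Phi) = mean over views and detector pixels of (P - G)^2

where P are the differentiable forward projections of the currently rendered
occupancy volume and G the input projections.  One iteration renders the
full voxel grid, projects it with the precomputed sparse operators,
backpropagates the residual through the projector, the MLP and the
interpolation stencils, and takes one Adam step.  After the final iteration
the rendered volume is binarized at 0.5 and small disconnected components
are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .field import (
    FieldConfig,
    FieldWeights,
    OccupancyVolume,
    mlp_backward,
    mlp_forward,
)
from .geometry import VolumeSpec
from .hash_encoder import HashEncoderConfig, HashTableSet, build_grid_cache
from .projector import ConeBeamProjector, Projection

__all__ = [
    "OptimizationConfig",
    "ReconstructionResult",
    "mse_loss",
    "optimize",
    "projection_loss_and_grads",
    "binarize_and_clean",
]


@dataclass(frozen=True)
class OptimizationConfig:
    """Hyperparameters of the per-subject fit."""

    iterations: int = 5000
    learning_rate: float = 1e-4
    log_every: int = 100
    seed: int = 0
    binarization_threshold: float = 0.5
    min_component_voxels: int = 25

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 < self.binarization_threshold < 1.0:
            raise ValueError("binarization threshold must lie in (0, 1)")
        if self.log_every < 1:
            raise ValueError("log_every must be >= 1")


@dataclass
class ReconstructionResult:
    occupancy: OccupancyVolume
    binary: np.ndarray
    loss_history: np.ndarray
    metric_history: list = field(default_factory=list)
    tables: HashTableSet | None = None
    weights: FieldWeights | None = None


def mse_loss(simulated, reference) -> float:
    """Mean squared pixel difference over all views and detector pixels."""
    sims = [s.image if isinstance(s, Projection) else np.asarray(s) for s in simulated]
    refs = [r.image if isinstance(r, Projection) else np.asarray(r) for r in reference]
    if len(sims) != len(refs):
        raise ValueError(f"view counts differ: {len(sims)} vs {len(refs)}")
    total = 0.0
    count = 0
    for s, r in zip(sims, refs):
        if s.shape != r.shape:
            raise ValueError(f"projection shapes differ: {s.shape} vs {r.shape}")
        d = s - r
        total += float(np.dot(d.ravel(), d.ravel()))
        count += d.size
    return total / count


class _Adam:
    """First-order adaptive optimizer with bias-corrected moments."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def binarize_and_clean(
    occ: OccupancyVolume | np.ndarray, cfg: OptimizationConfig
) -> np.ndarray:
    """Threshold occupancy and drop small disconnected components.

    A voxel is foreground iff occupancy > threshold (ties to background);
    then every 26-connected component with fewer than
    ``cfg.min_component_voxels`` voxels is removed.
    """
    values = occ.values if isinstance(occ, OccupancyVolume) else np.asarray(occ)
    binary = values > cfg.binarization_threshold
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n_comp = ndimage.label(binary, structure=structure)
    if n_comp:
        counts = np.bincount(labels.ravel())
        keep = counts >= cfg.min_component_voxels
        keep[0] = False
        binary = keep[labels]
    return binary.astype(np.uint8)


def projection_loss_and_grads(
    tables: HashTableSet,
    weights: FieldWeights,
    cache,
    matrices: list,
    refs: list[np.ndarray],
):
    """One evaluation of the reprojection loss and its exact gradients.

    ``matrices`` are the per-view sparse projection operators, ``refs`` the
    flattened reference images.  Returns (loss, rendered occupancy vector,
    gradient w.r.t. the tables, per-layer (dW, db) gradients).  This is the
    inner computation of :func:`optimize`, exposed so gradients can be
    validated against finite differences on the identical code path.
    """
    feats = cache.encode(tables)
    occ, mlp_cache = mlp_forward(feats, weights, want_cache=True)
    n_pix_total = sum(r.size for r in refs)
    loss = 0.0
    d_occ = np.zeros_like(occ)
    for mat, ref in zip(matrices, refs):
        resid = mat @ occ - ref
        loss += float(np.dot(resid, resid))
        d_occ += mat.T @ resid
    loss /= n_pix_total
    d_occ *= 2.0 / n_pix_total
    layer_grads, d_feats = mlp_backward(d_occ, weights, mlp_cache, occ)
    d_tables = cache.backward(d_feats)
    return loss, occ, d_tables, layer_grads


def optimize(
    projections: list[Projection],
    cfg: OptimizationConfig,
    enc_cfg: HashEncoderConfig,
    vol: VolumeSpec,
    field_cfg: FieldConfig | None = None,
    ground_truth: np.ndarray | None = None,
    projector_step: float | None = None,
    callback=None,
    dtype=np.float32,
) -> ReconstructionResult:
    """Fit the occupancy field to the input projections.

    Parameters
    ----------
    projections : the N input views (images + geometry).
    cfg, enc_cfg, vol : optimization, encoder and grid configuration.
    field_cfg : MLP architecture; default 8 layers x 256 wide.
    ground_truth : optional binary volume; when given, the six evaluation
        metrics of the cleaned intermediate reconstruction are recorded every
        ``cfg.log_every`` iterations.
    callback : optional ``f(iteration, loss)`` hook.
    """
    if not projections:
        raise ValueError("need at least one input projection")
    if field_cfg is None:
        field_cfg = FieldConfig(input_dim=enc_cfg.feature_dim)
    if field_cfg.input_dim != enc_cfg.feature_dim:
        raise ValueError("field input width must equal encoder feature dim")

    from .metrics import evaluate  # deferred: metrics import scikit-image

    cache = build_grid_cache(enc_cfg, vol, dtype=dtype)
    ops = [
        ConeBeamProjector(p.geometry, vol, projector_step, dtype=dtype)
        for p in projections
    ]
    refs = [np.asarray(p.image, dtype=dtype).ravel() for p in projections]

    tables = HashTableSet.initialize(enc_cfg, seed=cfg.seed, dtype=dtype)
    weights = FieldWeights.initialize(field_cfg, seed=cfg.seed + 1, dtype=dtype)

    params = [tables.values] + weights.ravel()
    adam = _Adam(params, lr=cfg.learning_rate)

    loss_history = np.empty(cfg.iterations)
    metric_history: list[tuple[int, object]] = []

    for it in range(cfg.iterations):
        loss, occ, d_tables, layer_grads = projection_loss_and_grads(
            tables, weights, cache, [op.matrix for op in ops], refs
        )
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite projection loss at iteration {it}; "
                "check inputs and learning rate"
            )
        loss_history[it] = loss

        grads = [d_tables]
        for gw, gb in layer_grads:
            grads.extend((gw, gb))
        adam.step(grads)

        if callback is not None:
            callback(it, loss)
        if ground_truth is not None and (it + 1) % cfg.log_every == 0:
            snap = binarize_and_clean(occ.reshape(vol.size), cfg)
            metric_history.append(
                (it + 1, evaluate(snap, ground_truth, vol.spacing))
            )

    feats = cache.encode(tables)
    occ = mlp_forward(feats, weights)
    occupancy = OccupancyVolume(occ.reshape(vol.size), vol)
    binary = binarize_and_clean(occupancy, cfg)
    return ReconstructionResult(
        occupancy=occupancy,
        binary=binary,
        loss_history=loss_history,
        metric_history=metric_history,
        tables=tables,
        weights=weights,
    )
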