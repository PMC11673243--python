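"""Residual MLP occupancy field.

Maps a multiresolution feature vector to an occupancy value in (0, 1) via a
fully connected network: LeakyReLU hidden activations, a sigmoid on the
output, and a mid-network skip that concatenates the encoded input back onto
the activations entering the middle layer (the widths differ, so the skip is
a concatenation rather than an addition).  The default profile is 8 weight
layers of width 256; a reduced profile is used for desk-scale runs.

Forward and backward passes are written against plain numpy arrays; the
backward pass returns exact analytic gradients for every weight, bias and the
input features (used to propagate into the hash tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import VolumeSpec, voxel_center_grid
from .hash_encoder import HashEncoderConfig, HashTableSet, encode

__all__ = [
    "FieldConfig",
    "FieldWeights",
    "OccupancyVolume",
    "mlp_forward",
    "mlp_backward",
    "predict_occupancy",
    "render_volume",
]


@dataclass(frozen=True)
class FieldConfig:
    """Architecture of the occupancy MLP."""

    input_dim: int
    num_layers: int = 8
    hidden_width: int = 256
    skip_layer: int | None = None  # 1-based; default = middle (num_layers//2 + 1)
    negative_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.num_layers < 2:
            raise ValueError("need at least 2 layers")
        if self.hidden_width < 1:
            raise ValueError("hidden width must be >= 1")
        skip = self.skip_layer
        if skip is None:
            object.__setattr__(self, "skip_layer", self.num_layers // 2 + 1)
        elif not (1 < skip <= self.num_layers):
            raise ValueError("skip_layer must lie strictly inside the network")


@dataclass
class OccupancyVolume:
    """A 3D grid of occupancy values in [0, 1] with physical spacing."""

    values: np.ndarray
    spec: VolumeSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != tuple(self.spec.size):
            raise ValueError(
                f"values shape {self.values.shape} != volume size {self.spec.size}"
            )
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("occupancy values must lie in [0, 1]")


class FieldWeights:
    """Trainable weights Phi of the occupancy MLP (list of (W, b) pairs)."""

    def __init__(self, layers: list[tuple[np.ndarray, np.ndarray]], cfg: FieldConfig):
        if len(layers) != cfg.num_layers:
            raise ValueError(f"expected {cfg.num_layers} layers, got {len(layers)}")
        self.layers = layers
        self.cfg = cfg

    @classmethod
    def initialize(cls, cfg: FieldConfig, seed: int, dtype=np.float64) -> "FieldWeights":
        """Fan-in uniform init U(-1/sqrt(fan_in), 1/sqrt(fan_in)), seeded."""
        rng = np.random.default_rng(seed)
        layers = []
        for i in range(1, cfg.num_layers + 1):
            fan_in = cls._layer_input_width(cfg, i)
            fan_out = 1 if i == cfg.num_layers else cfg.hidden_width
            bound = 1.0 / np.sqrt(fan_in)
            w = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(dtype)
            b = rng.uniform(-bound, bound, size=(fan_out,)).astype(dtype)
            layers.append((w, b))
        return cls(layers, cfg)

    @staticmethod
    def _layer_input_width(cfg: FieldConfig, layer: int) -> int:
        if layer == 1:
            return cfg.input_dim
        if layer == cfg.skip_layer:
            return cfg.hidden_width + cfg.input_dim
        return cfg.hidden_width

    def ravel(self) -> list[np.ndarray]:
        """Flat list of parameter arrays (for the optimizer)."""
        out: list[np.ndarray] = []
        for w, b in self.layers:
            out.extend((w, b))
        return out


def _leaky_relu(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, z, slope * z)


def mlp_forward(
    x: np.ndarray, weights: FieldWeights, want_cache: bool = False
):
    """Occupancy for a batch of feature vectors, shape (n, input_dim) -> (n,).

    With ``want_cache`` the per-layer inputs and pre-activations needed by
    :func:`mlp_backward` are returned as well.
    """
    cfg = weights.cfg
    x = np.atleast_2d(np.asarray(x))
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    if x.shape[1] != cfg.input_dim:
        raise ValueError(
            f"feature width {x.shape[1]} != configured input width {cfg.input_dim}"
        )
    h = x
    cache = []
    for i, (w, b) in enumerate(weights.layers, start=1):
        if i == cfg.skip_layer:
            h = np.concatenate([h, x], axis=1)
        z = h @ w + b
        cache.append((h, z))
        if i < cfg.num_layers:
            h = _leaky_relu(z, cfg.negative_slope)
    out = z.dtype.type(1.0) / (z.dtype.type(1.0) + np.exp(-z[:, 0]))
    if want_cache:
        return out, cache
    return out


def mlp_backward(d_out: np.ndarray, weights: FieldWeights, cache, out: np.ndarray):
    """Backpropagate d(loss)/d(occupancy) through the network.

    Returns (gradients for each (W, b) in layer order, gradient w.r.t. the
    input feature vectors).
    """
    cfg = weights.cfg
    # through the sigmoid
    delta = (d_out * out * (1.0 - out))[:, None]
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * cfg.num_layers
    d_x = None
    for i in range(cfg.num_layers, 0, -1):
        w, _ = weights.layers[i - 1]
        h_in, z = cache[i - 1]
        if i < cfg.num_layers:
            one = z.dtype.type(1.0)
            slope = z.dtype.type(cfg.negative_slope)
            delta = delta * np.where(z > 0, one, slope)
        grads[i - 1] = (h_in.T @ delta, delta.sum(axis=0))
        d_h = delta @ w.T
        if i == cfg.skip_layer:
            width = cfg.hidden_width if i > 1 else cfg.input_dim
            d_skip = d_h[:, width:]
            d_x = d_skip if d_x is None else d_x + d_skip
            d_h = d_h[:, :width]
        if i == 1:
            d_x = d_h if d_x is None else d_x + d_h
        delta = d_h
    return grads, d_x


def predict_occupancy(features: np.ndarray, weights: FieldWeights) -> np.ndarray:
    """Occupancy in (0, 1) for one feature vector or a batch."""
    out = mlp_forward(features, weights)
    return out if np.asarray(features).ndim == 2 else float(out[0])


def render_volume(
    weights: FieldWeights,
    tables: HashTableSet,
    enc_cfg: HashEncoderConfig,
    vol: VolumeSpec,
    chunk_size: int | None = None,
) -> OccupancyVolume:
    """Evaluate encode -> MLP at every voxel center of the grid.

    Evaluation is pointwise, so the result is independent of ``chunk_size``.
    """
    pts = voxel_center_grid(vol)
    n = pts.shape[0]
    chunk = n if chunk_size is None else int(chunk_size)
    out = np.empty(n)
    for start in range(0, n, chunk):
        feats = encode(pts[start : start + chunk], tables, enc_cfg, vol.extent)
        out[start : start + chunk] = mlp_forward(feats, weights)
    return OccupancyVolume(out.reshape(vol.size), vol)
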