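"""Multiresolution hash encoding of 3D coordinates.

A point in the (centered, physical-mm) volume is featurized at L grid
resolutions N_l = N_min * b**l.  At each level the point's enclosing grid
cell is found, the feature vectors stored at the cell's 8 vertices are looked
up in a learnable table of T rows x F features, trilinearly interpolated, and
the per-level results concatenated into a length L*F vector.  Coarse levels
with (N_l+1)^3 <= T index vertices one-to-one (collision-free row-major
linearization); finer levels index through a spatial hash

    h(v) = (v_1*pi_1 XOR v_2*pi_2 XOR v_3*pi_3) mod T

with fixed primes and unsigned 32-bit wraparound products.  Hash collisions
are left unresolved at lookup time; gradient-based optimization down-weights
them automatically.  The tables are the encoder's only trainable parameters.

For repeated evaluation on a fixed voxel grid the interpolation stencil is
precomputed once as one sparse matrix per level (8 weights per point), which
makes both encoding and its exact gradient a sparse matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import VolumeSpec, voxel_center_grid

__all__ = [
    "HashEncoderConfig",
    "HashTableSet",
    "level_resolution",
    "vertex_index",
    "encode",
    "GridEncodingCache",
    "build_grid_cache",
]

# Primes of the classic 3D spatial hash; pi_1 = 1 keeps the x-axis coherent.
_PRIMES = np.array([1, 2654435761, 805459861], dtype=np.uint32)


@dataclass(frozen=True)
class HashEncoderConfig:
    """Hyperparameters of the multiresolution hash encoder."""

    levels: int = 16
    table_size: int = 2**19
    features_per_entry: int = 2
    coarsest_resolution: int = 16
    growth_factor: float = 2.0
    input_dim: int = 3

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        t = self.table_size
        if t < 1 or (t & (t - 1)) != 0:
            raise ValueError(f"table_size must be a power of two, got {t}")
        if self.features_per_entry < 1:
            raise ValueError("features_per_entry must be >= 1")
        if self.coarsest_resolution < 1:
            raise ValueError("coarsest_resolution must be >= 1")
        if self.growth_factor <= 1.0:
            raise ValueError("growth_factor must be > 1")
        if self.input_dim != 3:
            raise ValueError("only 3D input is supported")

    @property
    def feature_dim(self) -> int:
        """Length L*F of the concatenated feature vector."""
        return self.levels * self.features_per_entry

    @property
    def finest_resolution(self) -> int:
        return level_resolution(self.levels - 1, self)


def level_resolution(level: int, cfg: HashEncoderConfig) -> int:
    """Grid resolution N_l = round(N_min * b**l) of one level."""
    if not 0 <= level < cfg.levels:
        raise ValueError(f"level {level} outside [0, {cfg.levels})")
    return int(round(cfg.coarsest_resolution * cfg.growth_factor**level))


def _is_direct(n_l: int, cfg: HashEncoderConfig) -> bool:
    return (n_l + 1) ** 3 <= cfg.table_size


def vertex_index(
    vertex: np.ndarray, n_l: int, cfg: HashEncoderConfig
) -> np.ndarray:
    """Table row index for integer grid vertices at resolution ``n_l``.

    Coarse levels ((N_l+1)^3 <= T) use the collision-free row-major
    linearization; finer levels the XOR spatial hash with mod-T realized as a
    bitwise AND (T is a power of two).
    """
    v = np.asarray(vertex)
    if v.shape[-1] != 3:
        raise ValueError("vertex must have trailing dimension 3")
    if np.any(v < 0) or np.any(v > n_l):
        raise ValueError(f"vertex outside grid [0, {n_l}]^3")
    if _is_direct(n_l, cfg):
        stride = n_l + 1
        return (v[..., 0] * stride + v[..., 1]) * stride + v[..., 2]
    vu = v.astype(np.uint32)
    with np.errstate(over="ignore"):
        h = (vu[..., 0] * _PRIMES[0]) ^ (vu[..., 1] * _PRIMES[1]) ^ (
            vu[..., 2] * _PRIMES[2]
        )
    return (h & np.uint32(cfg.table_size - 1)).astype(np.int64)


class HashTableSet:
    """The trainable per-level feature tables, shape (L, T, F)."""

    def __init__(self, values: np.ndarray, cfg: HashEncoderConfig, seed: int | None = None):
        expected = (cfg.levels, cfg.table_size, cfg.features_per_entry)
        values = np.asarray(values)
        if not np.issubdtype(values.dtype, np.floating):
            values = values.astype(np.float64)
        if values.shape != expected:
            raise ValueError(f"table shape {values.shape} != {expected}")
        if not np.all(np.isfinite(values)):
            raise ValueError("table entries must be finite")
        self.values = values
        self.cfg = cfg
        self.seed = seed

    @classmethod
    def initialize(
        cls, cfg: HashEncoderConfig, seed: int, scale: float = 1e-4,
        dtype=np.float64,
    ) -> "HashTableSet":
        """Small symmetric uniform init in [-scale, scale], seeded."""
        rng = np.random.default_rng(seed)
        shape = (cfg.levels, cfg.table_size, cfg.features_per_entry)
        return cls(rng.uniform(-scale, scale, size=shape).astype(dtype), cfg, seed=seed)

    @property
    def num_parameters(self) -> int:
        return self.values.size


def _cell_and_weights(points: np.ndarray, n_l: int, extent: np.ndarray):
    """Locate each point's grid cell at one level and its trilinear weights.

    points are centered physical coordinates; the volume extent is mapped
    onto [0, N_l]^3.  Points on the upper boundary are clamped into the last
    cell.  Returns (corner vertex indices (n, 8, 3), weights (n, 8)).
    """
    u = (points / extent + 0.5) * n_l
    u = np.clip(u, 0.0, np.nextafter(float(n_l), 0.0))
    i0 = np.minimum(np.floor(u).astype(np.int64), n_l - 1)
    frac = u - i0
    offs = np.array(
        [[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)], dtype=np.int64
    )
    corners = i0[:, None, :] + offs[None, :, :]  # (n, 8, 3)
    w = np.ones((points.shape[0], 8), dtype=points.dtype)
    for axis in range(3):
        f = frac[:, axis][:, None]
        w = w * np.where(offs[None, :, axis] == 1, f, 1.0 - f)
    return corners, w


def encode(
    points: np.ndarray,
    tables: HashTableSet,
    cfg: HashEncoderConfig,
    vol_extent,
) -> np.ndarray:
    """Encode centered physical points (mm) into (n, L*F) feature vectors.

    Per level the point is rescaled to the level grid, its cell's 8 vertex
    features gathered through :func:`vertex_index` and trilinearly
    interpolated; levels are concatenated coarse-to-fine.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.shape[-1] != 3:
        raise ValueError("points must have trailing dimension 3")
    extent = np.asarray(vol_extent, dtype=np.float64)
    half = extent / 2.0
    if np.any(pts < -half - 1e-9) or np.any(pts > half + 1e-9):
        raise ValueError("point outside the physical volume bounds")
    out = np.empty((pts.shape[0], cfg.feature_dim), dtype=np.float64)
    f = cfg.features_per_entry
    for level in range(cfg.levels):
        n_l = level_resolution(level, cfg)
        corners, w = _cell_and_weights(pts, n_l, extent)
        rows = vertex_index(corners, n_l, cfg)  # (n, 8)
        feats = tables.values[level][rows]  # (n, 8, F)
        out[:, level * f : (level + 1) * f] = np.einsum("nk,nkf->nf", w, feats)
    return out if np.asarray(points).ndim == 2 else out[0]


@dataclass
class GridEncodingCache:
    """Precomputed per-level interpolation stencils for a fixed voxel grid.

    ``stencils[l]`` is a sparse (num_voxels, T) matrix S_l with the 8
    trilinear gather weights of every voxel center, so the level-l features
    are ``S_l @ tables[l]`` and the exact parameter gradient is
    ``S_l.T @ d_features_l``.
    """

    cfg: HashEncoderConfig
    vol: VolumeSpec
    stencils: list

    def encode(self, tables: HashTableSet) -> np.ndarray:
        f = self.cfg.features_per_entry
        out = np.empty(
            (self.vol.num_voxels, self.cfg.feature_dim), dtype=tables.values.dtype
        )
        for level, s_mat in enumerate(self.stencils):
            out[:, level * f : (level + 1) * f] = s_mat @ tables.values[level]
        return out

    def backward(self, d_features: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. the tables, shape (L, T, F)."""
        f = self.cfg.features_per_entry
        grad = np.empty(
            (self.cfg.levels, self.cfg.table_size, f), dtype=d_features.dtype
        )
        for level, s_mat in enumerate(self.stencils):
            grad[level] = s_mat.T @ d_features[:, level * f : (level + 1) * f]
        return grad


def build_grid_cache(
    cfg: HashEncoderConfig, vol: VolumeSpec, dtype=np.float64
) -> GridEncodingCache:
    """Build the sparse interpolation stencils for every voxel center."""
    pts = voxel_center_grid(vol)
    extent = np.asarray(vol.extent)
    n_pts = pts.shape[0]
    stencils = []
    for level in range(cfg.levels):
        n_l = level_resolution(level, cfg)
        corners, w = _cell_and_weights(pts, n_l, extent)
        rows = np.repeat(np.arange(n_pts, dtype=np.int64), 8)
        cols = vertex_index(corners, n_l, cfg).ravel()
        s_mat = sp.coo_matrix(
            (w.ravel().astype(dtype), (rows, cols)), shape=(n_pts, cfg.table_size)
        ).tocsr()
        s_mat.sum_duplicates()
        stencils.append(s_mat)
    return GridEncodingCache(cfg=cfg, vol=vol, stencils=stencils)
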