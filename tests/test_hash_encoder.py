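"""Multiresolution hash encoder: indexing, interpolation, gradients."""

import numpy as np
import pytest

from vesselfield import HashEncoderConfig, HashTableSet, VolumeSpec, encode
from vesselfield.geometry import voxel_center_grid
from vesselfield.hash_encoder import (
    build_grid_cache,
    level_resolution,
    vertex_index,
)


def scalar_hash(v, table_size: int) -> int:
    """Pure-integer spatial hash: 32-bit wraparound products, XOR, mod T."""
    h = (
        (v[0] * 1) % 2**32
        ^ (v[1] * 2654435761) % 2**32
        ^ (v[2] * 805459861) % 2**32
    )
    return h % table_size


def naive_encode_point(point, tables, cfg, extent):
    """Independent scalar reference: per-level cell lookup + trilinear mix."""
    point = np.asarray(point, dtype=float)
    extent = np.asarray(extent, dtype=float)
    out = []
    for level in range(cfg.levels):
        n_l = level_resolution(level, cfg)
        u = (point / extent + 0.5) * n_l
        u = np.minimum(np.maximum(u, 0.0), np.nextafter(float(n_l), 0.0))
        i0 = np.minimum(np.floor(u).astype(int), n_l - 1)
        f = u - i0
        acc = np.zeros(cfg.features_per_entry)
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    v = (i0[0] + dx, i0[1] + dy, i0[2] + dz)
                    if (n_l + 1) ** 3 <= cfg.table_size:
                        row = (v[0] * (n_l + 1) + v[1]) * (n_l + 1) + v[2]
                    else:
                        row = scalar_hash(v, cfg.table_size)
                    w = (
                        (f[0] if dx else 1 - f[0])
                        * (f[1] if dy else 1 - f[1])
                        * (f[2] if dz else 1 - f[2])
                    )
                    acc = acc + w * tables.values[level][row]
                    del w
        out.append(acc)
    return np.concatenate(out)


class TestLevelResolution:
    def test_clinical_hyperparameters(self):
        cfg = HashEncoderConfig()
        assert level_resolution(0, cfg) == 16
        assert level_resolution(1, cfg) == 32
        assert level_resolution(3, cfg) == 128

    def test_level_out_of_range(self):
        cfg = HashEncoderConfig(levels=4, table_size=2**8)
        with pytest.raises(ValueError):
            level_resolution(4, cfg)

    def test_table_size_must_be_power_of_two(self):
        with pytest.raises(ValueError):
            HashEncoderConfig(table_size=1000)


class TestVertexIndex:
    def test_direct_path_row_major(self):
        cfg = HashEncoderConfig()
        # (17)^3 = 4913 <= 2^19 -> collision-free linearization
        assert vertex_index(np.array([0, 0, 0]), 16, cfg) == 0
        assert vertex_index(np.array([0, 0, 1]), 16, cfg) == 1
        assert vertex_index(np.array([1, 0, 0]), 16, cfg) == 17 * 17

    def test_direct_path_is_injective(self):
        cfg = HashEncoderConfig(levels=2, table_size=2**8, coarsest_resolution=2)
        n_l = 4
        grid = np.stack(
            np.meshgrid(*[np.arange(n_l + 1)] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        idx = vertex_index(grid, n_l, cfg)
        assert len(np.unique(idx)) == len(grid)

    def test_hashed_path_matches_scalar_formula(self):
        cfg = HashEncoderConfig(levels=8, table_size=2**8, coarsest_resolution=4)
        n_l = 512  # (513)^3 > 2^8 -> hashed
        assert vertex_index(np.array([0, 0, 0]), n_l, cfg) == 0
        assert vertex_index(np.array([1, 0, 0]), n_l, cfg) == 1  # pi_1 = 1
        v = np.array([3, 5, 7])
        assert vertex_index(v, n_l, cfg) == scalar_hash((3, 5, 7), cfg.table_size)

    def test_collision_regime_boundary_at_clinical_table_size(self):
        cfg = HashEncoderConfig()
        assert (79 + 1) ** 3 <= cfg.table_size
        assert (80 + 1) ** 3 > cfg.table_size

    def test_vertex_outside_grid_rejected(self):
        cfg = HashEncoderConfig(levels=2, table_size=2**8, coarsest_resolution=2)
        with pytest.raises(ValueError):
            vertex_index(np.array([0, 5, 0]), 4, cfg)


class TestEncode:
    def test_feature_vector_length_is_levels_times_features(self):
        cfg = HashEncoderConfig()
        assert cfg.feature_dim == 32  # 16 levels x 2 features

    def test_point_on_vertex_returns_table_entry(self, tiny_encoder_cfg):
        cfg = tiny_encoder_cfg
        vol = VolumeSpec.isotropic(8, 1.0)
        tables = HashTableSet.initialize(cfg, seed=3, scale=1.0)
        # vertex (1,1,1) of level 0 (N_0 = 2) lies at the volume center
        feats = encode(np.zeros(3), tables, cfg, vol.extent)
        row = vertex_index(np.array([1, 1, 1]), 2, cfg)
        np.testing.assert_allclose(
            feats[:2], tables.values[0][row], rtol=0, atol=1e-12
        )

    def test_cell_center_is_mean_of_eight_vertices(self):
        cfg = HashEncoderConfig(
            levels=1, table_size=2**8, features_per_entry=2, coarsest_resolution=2
        )
        vol = VolumeSpec.isotropic(8, 1.0)
        tables = HashTableSet.initialize(cfg, seed=0, scale=1.0)
        # center of cell [0,1]x[0,1]x[0,1] at N=2: physical (-2,-2,-2)
        feats = encode(np.array([-2.0, -2.0, -2.0]), tables, cfg, vol.extent)
        corners = np.stack(
            np.meshgrid([0, 1], [0, 1], [0, 1], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        rows = vertex_index(corners, 2, cfg)
        np.testing.assert_allclose(feats, tables.values[0][rows].mean(axis=0), atol=1e-12)

    def test_matches_naive_reference_on_random_points(self, tiny_encoder_cfg, rng):
        cfg = tiny_encoder_cfg  # L=4, T=2^8
        vol = VolumeSpec.isotropic(16, 1.0)
        tables = HashTableSet.initialize(cfg, seed=5, scale=1.0)
        pts = rng.uniform(-7.9, 7.9, size=(120, 3))
        batch = encode(pts, tables, cfg, vol.extent)
        for k in range(len(pts)):
            np.testing.assert_allclose(
                batch[k],
                naive_encode_point(pts[k], tables, cfg, vol.extent),
                rtol=0,
                atol=1e-12,
            )

    def test_continuity_across_cell_faces(self, tiny_encoder_cfg, rng):
        cfg = tiny_encoder_cfg
        vol = VolumeSpec.isotropic(16, 1.0)
        tables = HashTableSet.initialize(cfg, seed=6, scale=1.0)
        # points straddling the x = 0 face of every level grid
        eps = 1e-9
        for _ in range(20):
            yz = rng.uniform(-7.0, 7.0, size=2)
            left = encode(np.array([-eps, *yz]), tables, cfg, vol.extent)
            right = encode(np.array([eps, *yz]), tables, cfg, vol.extent)
            np.testing.assert_allclose(left, right, atol=1e-6)

    def test_point_outside_bounds_rejected(self, tiny_encoder_cfg):
        vol = VolumeSpec.isotropic(8, 1.0)
        tables = HashTableSet.initialize(tiny_encoder_cfg, seed=0)
        with pytest.raises(ValueError):
            encode(np.array([10.0, 0.0, 0.0]), tables, tiny_encoder_cfg, vol.extent)

    def test_table_perturbation_moves_output_by_weight(self, tiny_encoder_cfg, rng):
        """First-order response to a table entry equals its gather weight."""
        cfg = tiny_encoder_cfg
        vol = VolumeSpec.isotropic(8, 1.0)
        tables = HashTableSet.initialize(cfg, seed=7, scale=1.0)
        point = rng.uniform(-3.0, 3.0, size=3)
        base = encode(point, tables, cfg, vol.extent)
        level, feat = 1, 0
        # find a touched row: perturb every row it could be and check linearity
        n_l = level_resolution(level, cfg)
        u = (point / np.asarray(vol.extent) + 0.5) * n_l
        i0 = np.floor(u).astype(int)
        row = vertex_index(i0, n_l, cfg)  # the (0,0,0) corner
        frac = u - i0
        weight = np.prod(1.0 - frac)
        eps = 0.125
        tables.values[level][row, feat] += eps
        moved = encode(point, tables, cfg, vol.extent)
        delta = moved - base
        slot = level * cfg.features_per_entry + feat
        assert delta[slot] == pytest.approx(weight * eps, rel=1e-9)


class TestGridCache:
    def test_cache_matches_pointwise_encode(self, tiny_encoder_cfg):
        cfg = tiny_encoder_cfg
        vol = VolumeSpec.isotropic(6, 1.5)
        tables = HashTableSet.initialize(cfg, seed=9, scale=1.0)
        cache = build_grid_cache(cfg, vol)
        direct = encode(voxel_center_grid(vol), tables, cfg, vol.extent)
        np.testing.assert_allclose(cache.encode(tables), direct, atol=1e-12)

    def test_cache_backward_is_exact_transpose(self, tiny_encoder_cfg, rng):
        cfg = tiny_encoder_cfg
        vol = VolumeSpec.isotropic(4, 1.0)
        cache = build_grid_cache(cfg, vol)
        d_feats = rng.standard_normal((vol.num_voxels, cfg.feature_dim))
        grad = cache.backward(d_feats)
        # <S t, d> == <t, S^T d> for random tables
        tables = HashTableSet.initialize(cfg, seed=1, scale=1.0)
        lhs = float(np.sum(cache.encode(tables) * d_feats))
        rhs = float(np.sum(tables.values * grad))
        assert lhs == pytest.approx(rhs, rel=1e-10)
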