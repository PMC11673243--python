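"""Named configuration profiles.

``paper``: the full-fidelity clinical configuration — 128^3 volume over a
90 mm field of view, 512^2 detector, 16-level hash encoder with 2^19-row
tables, 8x256 MLP, 5000 Adam iterations at learning rate 1e-4.  This scale
is intended for long (order GPU-hour equivalent) runs.

``test``: a desk-scale configuration that keeps clinical voxel pitch but
shrinks the field of view to a 22.5 mm coronary subvolume (32^3 voxels,
64^2 detector), with a proportionally reduced encoder (8 levels, 2^14-row
tables) and MLP (4x64) and a larger learning rate (1e-3, the usual Adam
default regime for small networks).  The whole two-view fit runs in minutes
on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .field import FieldConfig
from .geometry import DetectorSpec, VolumeSpec
from .hash_encoder import HashEncoderConfig
from .reconstruct import OptimizationConfig

__all__ = ["Profile", "get_profile"]


@dataclass(frozen=True)
class Profile:
    name: str
    vol: VolumeSpec
    detector: DetectorSpec
    encoder: HashEncoderConfig
    field: FieldConfig
    optimization: OptimizationConfig

    def with_seed(self, seed: int) -> "Profile":
        return replace(self, optimization=replace(self.optimization, seed=seed))


def get_profile(name: str, seed: int = 0) -> Profile:
    if name == "paper":
        enc = HashEncoderConfig(
            levels=16,
            table_size=2**19,
            features_per_entry=2,
            coarsest_resolution=16,
            growth_factor=2.0,
        )
        return Profile(
            name="paper",
            vol=VolumeSpec.isotropic(128, 0.703125),
            detector=DetectorSpec((512, 512), (0.2779, 0.2779)),
            encoder=enc,
            field=FieldConfig(input_dim=enc.feature_dim, num_layers=8, hidden_width=256),
            optimization=OptimizationConfig(
                iterations=5000, learning_rate=1e-4, seed=seed
            ),
        )
    if name == "test":
        enc = HashEncoderConfig(
            levels=8,
            table_size=2**14,
            features_per_entry=2,
            coarsest_resolution=4,
            growth_factor=2.0,
        )
        return Profile(
            name="test",
            vol=VolumeSpec.isotropic(32, 0.703125),
            detector=DetectorSpec((64, 64), (1.0, 1.0)),
            encoder=enc,
            field=FieldConfig(input_dim=enc.feature_dim, num_layers=4, hidden_width=64),
            optimization=OptimizationConfig(
                iterations=800, learning_rate=1e-3, seed=seed
            ),
        )
    raise ValueError(f"unknown profile {name!r}; choose 'test' or 'paper'")
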