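import numpy as np
import pytest

from vesselfield import (
    ConeBeamGeometry,
    DetectorSpec,
    FieldConfig,
    HashEncoderConfig,
    VolumeSpec,
)


@pytest.fixture
def small_vol() -> VolumeSpec:
    return VolumeSpec.isotropic(8, 2.0)


@pytest.fixture
def small_detector() -> DetectorSpec:
    return DetectorSpec((16, 16), (2.0, 2.0))


@pytest.fixture
def small_geom(small_detector) -> ConeBeamGeometry:
    return ConeBeamGeometry(1000.0, 750.0, 20.0, -5.0, small_detector)


@pytest.fixture
def tiny_encoder_cfg() -> HashEncoderConfig:
    return HashEncoderConfig(
        levels=4, table_size=2**8, features_per_entry=2, coarsest_resolution=2
    )


@pytest.fixture
def tiny_field_cfg(tiny_encoder_cfg) -> FieldConfig:
    return FieldConfig(
        input_dim=tiny_encoder_cfg.feature_dim, num_layers=4, hidden_width=16
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
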