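from __future__ import annotations

import numpy as np
import pytest

from mitoquant.core import AcquisitionGeometry
from mitoquant.synth.mito import MitoScenario, NoiseModel

# Small fields keep the suite fast while preserving the axial geometry of the
# two acquisition protocols (10 slices @ 0.25 µm; 12 slices @ 0.35 µm).


@pytest.fixture
def mito_geometry() -> AcquisitionGeometry:
    return AcquisitionGeometry(n_slices=10, voxel_z_um=0.25, n_frames=9, shape_yx=(96, 96))


@pytest.fixture
def vesicle_geometry() -> AcquisitionGeometry:
    return AcquisitionGeometry(n_slices=12, voxel_z_um=0.35, n_frames=1, shape_yx=(96, 96))


@pytest.fixture
def noise_free() -> NoiseModel:
    return NoiseModel(gaussian_sd=0.0, poisson_scaling=0.0)


@pytest.fixture
def small_mito_scenario(noise_free) -> MitoScenario:
    return MitoScenario(n_tubules=4, noise=noise_free)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
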