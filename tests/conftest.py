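import logging

import numpy as np
import pytest

import handsyn as hs

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def default_cfg() -> hs.SynthConfig:
    return hs.SynthConfig(seed=1)


@pytest.fixture(scope="session")
def posture_set(default_cfg) -> hs.PostureSet:
    return hs.generate_posture_set(default_cfg)


@pytest.fixture(scope="session")
def synergy_model(posture_set) -> hs.SynergyModel:
    return hs.extract_kinematic_synergies(hs.average_repetitions(posture_set), 5)


@pytest.fixture(scope="session")
def small_grid_cfg() -> hs.SynthConfig:
    """Desk-scale voxel grid for the heavier encoding tests."""
    return hs.SynthConfig(seed=3, grid_shape=(10, 10, 10), smoothness_fwhm=3.0)


@pytest.fixture(scope="session")
def small_encoding_cfg() -> hs.EncodingConfig:
    return hs.EncodingConfig(
        n_select_stage1=600, n_select_stage2=200, cluster_min_size=10, seed=7
    )


@pytest.fixture(scope="session")
def voxel_patterns(small_grid_cfg, synergy_model) -> hs.VoxelPatternSet:
    return hs.generate_voxel_patterns(synergy_model.weights, small_grid_cfg)
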