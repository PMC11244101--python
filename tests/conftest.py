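import numpy as np
import pytest

import radarid as ri


@pytest.fixture(scope="session")
def short_config() -> ri.RadarConfig:
    """Small cube geometry for fast unit tests (full 256-bin fast time)."""
    return ri.RadarConfig(n_frames=400)


@pytest.fixture(scope="session")
def bin26_profile(short_config) -> ri.SubjectProfile:
    """Subject parked exactly on range bin 26 (bin-centered: k = 2BR/c = 26)."""
    return ri.SubjectProfile("S00", nominal_range=26 * short_config.range_resolution,
                             breath_rate=0.25, breath_amplitude=2e-3,
                             heart_rate=1.1, heart_amplitude=1e-4)


@pytest.fixture(scope="session")
def clean_cube(short_config, bin26_profile) -> ri.RadarCube:
    """Noise-free, clutter-free cube: only the breathing subject."""
    return ri.synthesize_cube(bin26_profile, ri.SceneConfig(), short_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240621)
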