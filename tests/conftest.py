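import numpy as np
import pytest

from qisp import (
    ARCHETYPES,
    RenderParams,
    archetype_profile,
    generate_truth_profiles,
)

EVEN_MIX = {"vz_peak": 1 / 3, "iz_peak": 1 / 3, "cp_peak": 1 / 3}


@pytest.fixture(scope="session")
def three_archetype_truth():
    """60 noise-free profiles, 20 per single-peak archetype."""
    return generate_truth_profiles(60, EVEN_MIX, seed=1)


@pytest.fixture(scope="session")
def noise_free_render():
    return RenderParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def dual_peak_profile():
    """Dab1-like profile: peaks in the VZ and the cortical plate."""
    return archetype_profile(ARCHETYPES["dual_peak"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
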