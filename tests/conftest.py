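import numpy as np
import pytest
from hypothesis import settings

import microdamage as md

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """Coarse raster (same physical kernel, bigger pixels) for fast tests."""
    return md.PhantomSpec(pixel_pitch=0.12, image_shape=(90, 130), noise_sd=0.0)


@pytest.fixture(scope="session")
def small_spec_noisy():
    return md.PhantomSpec(pixel_pitch=0.12, image_shape=(90, 130), noise_sd=6.0)


@pytest.fixture(scope="session")
def baseline_scenario():
    return md.LoadScenario(load_type="static", orientation="vertical",
                           load_fraction=0.3, baseline_fraction=0.05)


@pytest.fixture(scope="session")
def fixed_mask(small_spec, baseline_scenario):
    """One deterministic phantom mask with ~5% damage."""
    _, mask, truth = md.generate_slice(small_spec, baseline_scenario, 0, seed=42)
    return mask, truth
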