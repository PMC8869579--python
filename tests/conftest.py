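import math

import numpy as np
import pytest

from lovewave import presets, synth
from lovewave.materials import load_material


@pytest.fixture(scope="session")
def ref_stack():
    return presets.reference_stack()


@pytest.fixture(scope="session")
def ref_device():
    return presets.reference_delay_line()


@pytest.fixture(scope="session")
def clean_config(ref_device, ref_stack):
    """Noise-free synthetic configuration on a small grid (fast)."""
    return synth.SynthConfig(
        device=ref_device, stack=ref_stack, wetted_path=presets.wetted_path(),
        f_start=20e6, f_stop=40e6, n_points=2001,
        noise_sigma=0.0, reflection=0.0, feedthrough_db=-math.inf, seed=7)


@pytest.fixture(scope="session")
def water():
    return load_material("water_25C")


@pytest.fixture(scope="session")
def water_spectrum(clean_config, water):
    return synth.synth_spectrum(clean_config, water)
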