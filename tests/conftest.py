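import math

import numpy as np
import pytest

from sxpre.core import Geometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def untilted_geometry():
    return Geometry(beam_center=(720.0, 720.0), distance_mm=100.0,
                    pixel_size_mm=0.1, photon_energy_ev=12000.0)


@pytest.fixture
def tilted_geometry():
    return Geometry(beam_center=(726.0, 715.0), distance_mm=100.0,
                    pixel_size_mm=0.1, photon_energy_ev=12000.0,
                    tilt_polar=0.02, tilt_azimuth=math.radians(30.0))


@pytest.fixture(scope="session")
def hit_dataset(tmp_path_factory):
    """50 synthetic frames with a 10% hit fraction, shared across tests."""
    from sxpre.synth import generate_dataset

    path = tmp_path_factory.mktemp("data") / "stack.h5"
    source, truth = generate_dataset(50, 0.1, path, seed=20240917)
    return source, truth
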