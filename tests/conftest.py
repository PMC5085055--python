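"""Shared fixtures.

Expensive forward simulations are session-scoped and deliberately coarse
(3 x 48 corneal elements, 27 frames): every physical property exercised by
the unit tests (monotonicity, symmetry, mirroring, round trips) holds at any
resolution, while the acceptance tests use the production resolution.
"""

from __future__ import annotations

import numpy as np
import pytest

from corneafit.airpuff import AirPuffLoad, AirPuffSimulator
from corneafit.geometry import CorneaGeometry
from corneafit.materials import MooneyRivlinParams
from corneafit.synthetic_data import phantom_params


@pytest.fixture(scope="session")
def mr_example() -> MooneyRivlinParams:
    """The worked-example material (c10=0.3, c01=0.1 MPa)."""
    return MooneyRivlinParams(0.3, 0.1)


@pytest.fixture(scope="session")
def coarse_load() -> AirPuffLoad:
    return AirPuffLoad(n_frames=27)


@pytest.fixture(scope="session")
def coarse_sim(coarse_load) -> AirPuffSimulator:
    return AirPuffSimulator(
        CorneaGeometry(thickness=0.45), 15.0, coarse_load,
        n_through_thickness=3, n_meridian=48,
    )


@pytest.fixture(scope="session")
def s_record(coarse_sim):
    """Full noiseless record of the mid phantom on the coarse model."""
    return coarse_sim.record(phantom_params("S"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
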