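import numpy as np
import pytest

from abtraj import (AngleSchedule, FluctuationSpec, GlobalMotion, GroundTruth,
                    Hinge, make_toy_antibody, simulate)


@pytest.fixture(scope="session")
def toy():
    """Default Y-shaped toy molecule (CA-only) and its domain map."""
    return make_toy_antibody()


@pytest.fixture(scope="session")
def toy_structure(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_map(toy):
    return toy[1]


@pytest.fixture(scope="session")
def rigid_tumble_traj(toy):
    """Zero-noise trajectory that only tumbles and drifts rigidly."""
    structure, dmap = toy
    truth = GroundTruth(
        fluctuation=FluctuationSpec(sigma=0.0),
        global_motion=GlobalMotion(rotation_axis=(0.3, 1.0, 0.2),
                                   rotation_rate_deg=4.0, drift=(0.5, -0.2, 0.1)),
        seed=11,
    )
    return simulate(structure, dmap, truth, 20)


@pytest.fixture(scope="session")
def noisy_traj(toy):
    """Static hinges + iid Gaussian noise, sigma = 0.5 Å per coordinate."""
    structure, dmap = toy
    truth = GroundTruth(fluctuation=FluctuationSpec(sigma=0.5), seed=7)
    return simulate(structure, dmap, truth, 300)


@pytest.fixture(scope="session")
def hinged_traj(toy):
    """Left hinge opens 0 -> 30 degrees with mild noise."""
    structure, dmap = toy
    truth = GroundTruth(
        hinges=[Hinge("left", AngleSchedule("ramp", start=0.0, end=30.0))],
        fluctuation=FluctuationSpec(sigma=0.3), seed=5,
    )
    return simulate(structure, dmap, truth, 200)


def random_cloud(rng, n=10, spread=10.0):
    return rng.uniform(-spread, spread, size=(n, 3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
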