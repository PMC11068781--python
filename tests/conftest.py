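import numpy as np
import pytest

from divekin import (
    RunConfig,
    SyntheticDiveSpec,
    analyze_synthetic_trial,
    generate_dive_3d,
    make_camera_rig,
)


@pytest.fixture(scope="session")
def rig():
    """The three-camera goal rig plus its surveyed control points."""
    return make_camera_rig("field3cam")


@pytest.fixture(scope="session")
def cameras(rig):
    return rig[0]


@pytest.fixture(scope="session")
def control_points(rig):
    return rig[1]


@pytest.fixture(scope="session")
def default_dive():
    """One noiseless default dive: (trajectory, ground truth)."""
    return generate_dive_3d(SyntheticDiveSpec())


@pytest.fixture(scope="session")
def analyzed_default(cameras):
    """Default dive pushed through the full pipeline at zero noise."""
    result, gt = analyze_synthetic_trial(SyntheticDiveSpec(), cameras)
    assert result.ok
    return result, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def config():
    return RunConfig()
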