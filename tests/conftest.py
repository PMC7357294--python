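import numpy as np
import pytest

from cerebroflow import GroundTruth, ParadigmSpec, gen_etco2_trace


@pytest.fixture(scope="session")
def noiseless_trace():
    """Default 12-min air/CO2 paradigm, one sample per 4-s breath, no noise."""
    return gen_etco2_trace(ParadigmSpec(), seed=0)


@pytest.fixture(scope="session")
def wm_truth():
    """Single-tissue ground truth: white-matter-like gain, 6 s delay."""
    return GroundTruth(cvr_gain={"wm": 0.03}, true_delay={"wm": 6.0})


@pytest.fixture(scope="session")
def two_tissue_truth():
    """Gray/white-matter pair with distinct gains and delays."""
    return GroundTruth(
        cvr_gain={"gm": 0.10, "wm": 0.03},
        true_delay={"gm": 4.0, "wm": 8.0},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
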