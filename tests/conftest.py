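"""Shared fixtures: small synthetic cohorts generated once per session."""

import numpy as np
import pytest

from crawlemg.features import build_dataset
from crawlemg.synth import SynthConfig, generate_cohort

MODES4 = ["M1", "M2", "M3", "M4"]
MODES8 = [f"M{i}" for i in range(1, 9)]


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig()


@pytest.fixture(scope="session")
def mini_cohort(synth_config):
    """3 participants x 4 modes x fast speed x 6 cycles (short trials)."""
    return generate_cohort(synth_config, 3, MODES4, ["fast"], 6, seed=11)


@pytest.fixture(scope="session")
def mini_dataset(mini_cohort):
    return build_dataset(mini_cohort)


@pytest.fixture(scope="session")
def noiseless_cohort(synth_config):
    """2 participants x 8 modes, fast, no stochastic spread anywhere."""
    return generate_cohort(synth_config.noiseless(), 2, MODES8, ["fast"], 6, seed=5)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_cohort):
    return build_dataset(noiseless_cohort)


@pytest.fixture(scope="session")
def default_low_cohort_dataset(synth_config):
    """The default study-scale cohort at low speed: 10 participants x 8 modes
    x 15 cycles, default variability.  Generated once; used by the evaluation
    protocol tests and the classification-analogue acceptance test."""
    trials = generate_cohort(synth_config, 10, MODES8, ["low"], 15, seed=1)
    return build_dataset(trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
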