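import logging

import numpy as np
import pytest

from alfapnc.glcm import GLCMParams
from alfapnc.pipeline import extract_features, screen_features
from alfapnc.scene import SceneParams, generate_dataset, generate_layout, generate_stage

logging.getLogger("alfapnc").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def layout():
    return generate_layout(0)


@pytest.fixture(scope="session")
def branching_stage():
    """One default branching-stage scene with ground truth (seed 1)."""
    ds = generate_dataset({"stages": ["branching"]}, seed=1)
    return ds["branching"]


@pytest.fixture(scope="session")
def branching_features(branching_stage):
    """Extracted feature table for the session's branching scene."""
    return extract_features(branching_stage, GLCMParams())


@pytest.fixture(scope="session")
def branching_screening(branching_features):
    return screen_features(branching_features)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
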