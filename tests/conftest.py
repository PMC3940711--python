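"""Shared fixtures: small synthetic datasets generated at module scope."""

import numpy as np
import pytest

from popddm import SequenceConfig, generate_study
from popddm.presets import SUBJECT_PRESETS


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def small_study():
    """One synthetic subject at the P1 reference parameters, full size."""
    return generate_study({"P1": SUBJECT_PRESETS["P1"]}, seed=101)


@pytest.fixture(scope="session")
def tiny_study():
    """A one-session study (320 trials/subject) for fast smoke fits."""
    cfg = SequenceConfig(sessions=1, subjects=["P1"])
    return generate_study({"P1": SUBJECT_PRESETS["P1"]}, cfg=cfg, seed=7)
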