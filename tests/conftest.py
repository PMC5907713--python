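"""Shared fixtures: small synthetic subjects and cohorts, built once per session."""

import dataclasses

import numpy as np
import pytest

from gaitclust.config import RunConfig
from gaitclust.synth import default_archetypes, make_cohort, make_subject


@pytest.fixture(scope="session")
def archetypes():
    return {a.name: a for a in default_archetypes()}


@pytest.fixture(scope="session")
def noise_free_subject(archetypes):
    """One noise-free female_C1 subject: the exact kinematics oracle."""
    return make_subject(archetypes["female_C1"], seed=3, noise_sd_mm=0.0)


@pytest.fixture(scope="session")
def noisy_subject(archetypes):
    """Same subject with default 0.5 mm marker noise."""
    return make_subject(archetypes["female_C1"], seed=3)


@pytest.fixture(scope="session")
def micro_cohort(archetypes):
    """Six females (3 C1, 3 C2) with shortened trials, for pipeline smokes."""
    specs = [
        dataclasses.replace(archetypes["female_C1"], n_subjects=3),
        dataclasses.replace(archetypes["female_C2"], n_subjects=3),
    ]
    return make_cohort(specs, seed=11, duration_s=10.0)


@pytest.fixture(scope="session")
def cfg():
    return RunConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
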