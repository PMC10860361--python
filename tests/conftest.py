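"""Shared fixtures: synthetic specimens and a small fitted cohort.

Session scope keeps mesh generation and the pipeline fit to one execution
each; tests must not mutate fixture objects.
"""

import numpy as np
import pytest
from hypothesis import settings

from subtalarsim import SubtalarLigamentModel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from subtalarsim.synthetic import SpecimenSpec, default_cohort_specs, generate_cohort, generate_specimen


@pytest.fixture(scope="session")
def noiseless_specimen():
    """Default right-foot specimen with exact (noise-free) landmarks."""
    return generate_specimen(SpecimenSpec(specimen_id="NL", seed=1, landmark_noise_sd=0.0))


@pytest.fixture(scope="session")
def cohort3():
    """Three-specimen cohort with the default 0.1 mm landmark noise."""
    return generate_cohort(default_cohort_specs(n=3, seed=0))


@pytest.fixture(scope="session")
def fit3(cohort3):
    """Fitted results on the three-specimen cohort (impingement check off:
    covered separately)."""
    model = SubtalarLigamentModel(cohort3)
    return model.fit(check_impingement=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
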