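import numpy as np
import pytest
from hypothesis import settings

import ribotraffic as rt

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

FULL_TIMEPOINTS = [-0.25, 0.0, 0.5, 1.0, 2.0, 4.0]


@pytest.fixture(scope="session")
def locus():
    return rt.build_locus({})


@pytest.fixture(scope="session")
def profile(locus):
    return rt.DamageRateProfile.default_piecewise(locus)


@pytest.fixture(scope="session")
def params():
    return rt.SimulationParams()


@pytest.fixture(scope="session")
def kinetics():
    return rt.RepairKinetics()


@pytest.fixture(scope="session")
def wt_trajectory(locus, profile, params, kinetics):
    """One full repair-proficient UV time course (shared across tests)."""
    return rt.run_scenario(locus, profile, params, kinetics,
                           FULL_TIMEPOINTS, seed=2024)


@pytest.fixture(scope="session")
def rad14_trajectory(locus, profile, params):
    """One full NER-deficient UV time course (shared across tests)."""
    return rt.run_scenario(locus, profile, params,
                           rt.RepairKinetics(ner_active=False),
                           FULL_TIMEPOINTS, seed=2024)


@pytest.fixture
def toy():
    return rt.gen_toy_fixture()
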