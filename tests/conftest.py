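import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from closedmcpmod import (
    CandidateModel,
    DoseDesign,
    TrialData,
    default_candidate_set,
)


@pytest.fixture(scope="session")
def case_design() -> DoseDesign:
    """The case-study design: doses 0/0.1/0.4/1, 100 patients per arm."""
    return DoseDesign((0.0, 0.1, 0.4, 1.0), (100, 100, 100, 100))


@pytest.fixture(scope="session")
def cset():
    return default_candidate_set()


@pytest.fixture(scope="session")
def emax2_truth() -> CandidateModel:
    return CandidateModel("emax", {"ed50": 0.2}, label="truth")


@pytest.fixture(scope="session")
def seeded_trial(case_design, emax2_truth) -> TrialData:
    """One deterministic trial under the Emax (ED50=0.2) truth, effect 0.4."""
    from closedmcpmod.simulate import Scenario, simulate_trial

    sc = Scenario(
        design=case_design, model=emax2_truth, effect=0.4, sigma=1.0,
        nsim=1, seed=20260929,
    )
    return simulate_trial(sc, 0)
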