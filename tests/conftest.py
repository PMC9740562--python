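import pytest
from hypothesis import settings

import mangoripen as mr

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def profiles():
    return mr.default_profiles()


@pytest.fixture(scope="session")
def bank():
    return mr.load_published_models()


@pytest.fixture(scope="session")
def calibration_obs():
    """One noisy five-variety calibration campaign (20 fruit each)."""
    return mr.simulate_campaign(mr.calibration_design(seed=123))


@pytest.fixture(scope="session")
def diourou_obs(profiles):
    """Noisy single-variety campaign used by the alpha/X duality checks."""
    design = mr.CampaignDesign(
        varieties=(profiles["Diourou"],), n_per_variety=20, seed=7
    )
    return mr.simulate_campaign(design)
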