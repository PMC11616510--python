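import pytest

from mnztreat import (CampaignSpec, KineticParameters, ReactorConfig,
                      generate_campaign)

#: Fitted field constants: k1 = 1.03e-4 1/s, km = 11.43 1/h, Kd = 4.49 L/g.
FIELD_K1 = 1.03e-4
FIELD_KM = 11.43 / 3600.0
FIELD_KD = 4.49


@pytest.fixture(scope="session")
def config():
    return ReactorConfig()


@pytest.fixture(scope="session")
def field_params():
    return KineticParameters(k1=FIELD_K1, km=FIELD_KM, kd=FIELD_KD)


@pytest.fixture(scope="session")
def initial_guess():
    """A deliberately off starting point for the optimiser."""
    return KineticParameters(k1=3e-5, km=1e-3, kd=1.0)


@pytest.fixture(scope="session")
def campaign_noiseless():
    return generate_campaign(CampaignSpec(seed=7, noise_cv=0.0))


@pytest.fixture(scope="session")
def campaign_noisy():
    return generate_campaign(CampaignSpec(seed=7, noise_cv=0.05))
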