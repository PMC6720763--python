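import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from odormix.reference import reference_profile, reference_profiles
from odormix.synthetic import default_sensor_model, simulate_enose_training
from odormix.fuzzy import FuzzyOdorModel


@pytest.fixture(scope="session")
def profiles():
    return reference_profiles()


@pytest.fixture(scope="session")
def toluene():
    return reference_profile("toluene")


@pytest.fixture(scope="session")
def noiseless_sensor_model(profiles):
    return default_sensor_model(profiles, noise_sd=0.0)


@pytest.fixture(scope="session")
def toluene_fuzzy_model(toluene, noiseless_sensor_model):
    """Fuzzy model calibrated on noiseless toluene samples at levels 1-5."""
    training = simulate_enose_training([toluene], noiseless_sensor_model,
                                       noise=False, seed=1)
    return FuzzyOdorModel.train(training)
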