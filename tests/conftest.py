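import pytest

from anaerodesign import ToyParams, make_toy_model, toy_intervention_library, toy_media
from anaerodesign.model_core import apply_medium


@pytest.fixture(scope="session")
def toy():
    """Default toy model with its planted truth."""
    return make_toy_model(ToyParams())


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def media():
    return toy_media(ToyParams())


@pytest.fixture(scope="session")
def toy_library():
    return toy_intervention_library(ToyParams())


@pytest.fixture()
def oxic_model(toy_model, media):
    return apply_medium(apply_medium(toy_model, media["minimal_glucose"]), media["oxic"])


@pytest.fixture()
def anoxic_model(toy_model, media):
    return apply_medium(apply_medium(toy_model, media["minimal_glucose"]), media["anoxic"])
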