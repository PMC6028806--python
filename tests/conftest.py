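import matplotlib

matplotlib.use("Agg")

import pytest

from simexpt import fixtures as fx


@pytest.fixture
def binding_model():
    return fx.make_binding_model()


@pytest.fixture
def cascade_model():
    return fx.make_cascade_model(3)


@pytest.fixture
def bistable_model():
    return fx.make_bistable_model()


@pytest.fixture(scope="session")
def translation():
    """(model, experiment doc) for the translation-initiation scenario."""
    return fx.make_translation_fixture()


@pytest.fixture(scope="session")
def hh_fixture():
    return fx.make_hh_fixture()
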