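import pytest

from nanoits import default_kb, dossier_fixture


@pytest.fixture(scope="session")
def kb():
    return default_kb()


@pytest.fixture()
def ionp():
    return dossier_fixture("ionp")


@pytest.fixture()
def iron_carbohydrate():
    return dossier_fixture("iron_carbohydrate")


@pytest.fixture()
def empty_dossier():
    return dossier_fixture("empty")
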