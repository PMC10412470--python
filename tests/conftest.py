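import pytest

from fontanvep import VEPCirculationModel, load_fixtures, pediatric_scenario


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def scenario():
    return pediatric_scenario()


@pytest.fixture(scope="session")
def results():
    """Model calibrated to the packaged fixtures on the 1-DO scenario."""
    return VEPCirculationModel().fit()


@pytest.fixture(scope="session")
def losses(results):
    return results.losses
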