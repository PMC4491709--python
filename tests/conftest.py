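import pytest
from hypothesis import settings

from ordmotif import load_catalog, make_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(params=["chain3", "fan_in3", "fan_out3", "triangle3", "random6", "random10"])
def fixture_net(request):
    return make_fixture(request.param, seed=1)
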