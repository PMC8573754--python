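import numpy as np
import pytest
from hypothesis import settings

from molcwater.forcefield import load_model

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

MODELS = ["SPC-E", "Tip3P-Ew", "Tip4P-05"]


@pytest.fixture(scope="session", params=MODELS)
def any_model(request):
    return load_model(request.param)


@pytest.fixture(scope="session")
def spce():
    return load_model("SPC-E")


@pytest.fixture(scope="session")
def tip4p():
    return load_model("Tip4P-05")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
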