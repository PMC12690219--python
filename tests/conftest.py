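import pytest
from hypothesis import settings

from osteocea.synthetic import make_default_params

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_params():
    params, _ = make_default_params()
    return params


@pytest.fixture(scope="session")
def manifest():
    _, m = make_default_params()
    return m
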