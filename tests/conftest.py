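import pytest

from mitorder import build_fixture_set, builtin_registry, prior_registry


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def prior():
    return prior_registry()


@pytest.fixture(scope="session")
def panel():
    return build_fixture_set(seed=0)


@pytest.fixture(scope="session")
def canonical(registry):
    return registry.canonical
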