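import random

import pytest

from belnet import FunctionRegistry, NamespaceRegistry


@pytest.fixture(scope="session")
def functions():
    return FunctionRegistry.default()


@pytest.fixture(scope="session")
def namespaces():
    return NamespaceRegistry.default()


@pytest.fixture()
def rng():
    return random.Random(20150520)
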