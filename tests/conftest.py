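import pytest

from vetregqa import load_locations, load_product_registry


@pytest.fixture(scope="session")
def registry():
    return load_product_registry()


@pytest.fixture(scope="session")
def locations():
    return load_locations()
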