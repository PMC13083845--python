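import pytest

from spliceaudit import load_model


@pytest.fixture(scope="session")
def model():
    return load_model()
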