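import pytest

from umitcr.decombine import TagMatcher
from umitcr.references import toy_reference


@pytest.fixture(scope="session")
def ref():
    return toy_reference()


@pytest.fixture(scope="session")
def matcher(ref):
    return TagMatcher(ref)
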