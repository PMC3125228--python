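import pytest

from mitosoma.haplogroups import bundled_tree
from mitosoma.reference import bundled_annotation, bundled_reference


@pytest.fixture(scope="session")
def reference():
    return bundled_reference()


@pytest.fixture(scope="session")
def annotation():
    return bundled_annotation()


@pytest.fixture(scope="session")
def tree(reference):
    return bundled_tree(reference)
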