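import pytest

from morphoclad import (
    apply_polarity_policy,
    laophontodes_matrix,
    reference_cladogram,
)


@pytest.fixture(scope="session")
def matrix():
    return laophontodes_matrix()


@pytest.fixture(scope="session")
def resolved(matrix):
    return apply_polarity_policy(matrix, "as-argued")


@pytest.fixture(scope="session")
def reference():
    return reference_cladogram()
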