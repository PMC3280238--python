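import pytest

from natx import synthdata


@pytest.fixture(scope="session")
def small_truth():
    """A small planted family reused across read-only tests."""
    return synthdata.generate_truth_bundle(
        n_subfamilies=3, taxa_per_subfamily=3, sub_rate=0.15, seed=11)


@pytest.fixture(scope="session")
def vector():
    return synthdata.mock_vector()
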