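import pytest

from pprescan import (
    PreferenceTier,
    consensus_at_threshold,
    default_scan_policy,
    encode_reference_model,
)


@pytest.fixture(scope="session")
def matrix():
    return encode_reference_model()


@pytest.fixture(scope="session")
def optimal_motif(matrix):
    return consensus_at_threshold(matrix, PreferenceTier.OPTIMAL_GT80)


@pytest.fixture(scope="session")
def scan_motif(matrix):
    """The relaxed 60-80% consensus used by the published promoter screen."""
    return consensus_at_threshold(matrix, PreferenceTier.ALLOWED_60_80)


@pytest.fixture(scope="session")
def scan_policy():
    return default_scan_policy(budget=1)
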