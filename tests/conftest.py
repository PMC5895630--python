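import numpy as np
import pytest

from nucscreen import generate_manifest, generate_truth
from nucscreen.manifest import LibraryMember


@pytest.fixture(scope="session")
def default_manifest():
    return generate_manifest(seed=0)


@pytest.fixture(scope="session")
def default_truth(default_manifest):
    return generate_truth(default_manifest, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def two_member_manifest():
    """Minimal library: one wt control and one experimental member, with
    barcodes at distance 8."""
    return [
        LibraryMember("wt_1", "AAAAAAAA", frozenset(), None, "wt_control"),
        LibraryMember("X", "CCCCCCCC", frozenset(), None, "experimental"),
    ]
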