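import numpy as np
import pytest

from opsinkit import synthio


@pytest.fixture(scope="session")
def repertoire():
    """Full nine-gene opsin repertoire at 1% per-copy paralog divergence."""
    records, diagnostics = synthio.make_repertoire(101, divergence=0.01)
    return records, diagnostics


@pytest.fixture(scope="session")
def small_library(repertoire):
    """An error-free 2,000-pair library from four genes, with truth."""
    records, _ = repertoire
    props = {"sws1a": 0.25, "rh2b": 0.30, "rh2a_1": 0.25, "rh1": 0.20}
    r1, r2, manifest = synthio.simulate_read_pairs(records, props, 2000, seed=7)
    reads = {n: (s1, s2) for (n, s1), (_, s2) in zip(r1, r2)}
    return records, reads, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
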