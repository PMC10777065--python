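import numpy as np
import pytest

from spbcmi import io_corpus, synthetic_data as sd


@pytest.fixture(scope="session")
def small_fixture():
    """A miniature dataset for fast end-to-end smoke tests."""
    spec = sd.FixtureSpec(
        n_circ=30, n_mir=16, n_blocks=2,
        circ_len_range=(60, 100), mir_len_range=(20, 28),
        seed=7,
    )
    return sd.gen_fixture(spec)


@pytest.fixture(scope="session")
def small_dataset(small_fixture):
    fx = small_fixture
    return io_corpus.build_interaction_set(
        fx.positive_pairs,
        [r.id for r in fx.circ_records],
        [r.id for r in fx.mir_records],
        seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
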