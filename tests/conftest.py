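import numpy as np
import pytest

import prionscan as ps


@pytest.fixture(scope="session")
def table():
    """The shipped prion-domain propensity table."""
    return ps.builtin_table()


@pytest.fixture(scope="session")
def proline_model():
    """The shipped (synthetic-reference) proline spacing model."""
    return ps.default_model()


@pytest.fixture(scope="session")
def toy_proline_model():
    """A tiny 5-distance model with distinct, hand-checkable log-odds."""
    counts = np.array([10, 5, 2, 2, 1])
    expected = np.full(5, 0.2)
    return ps.build_proline_model(counts, expected)


@pytest.fixture(scope="session")
def trained_proline_model():
    """A 60-distance model trained on seeded background sequences."""
    spec = ps.GeneratorSpec.background(min_length=100, max_length=300)
    records = ps.sample_sequences(spec, 300, seed=7)
    return ps.train_proline_model(records, max_distance=60)
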