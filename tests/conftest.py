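import numpy as np
import pytest

from sleeptransfer import FeatureTable


def make_table(X, labels=None, domain="source", subject=None, recording=None):
    """FeatureTable with minimal metadata for tests."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    return FeatureTable(
        X,
        np.zeros(n, dtype=int) if labels is None else np.asarray(labels),
        np.full(n, domain),
        np.full(n, "s0") if subject is None else np.asarray(subject),
        np.full(n, "r1") if recording is None else np.asarray(recording),
    )


@pytest.fixture
def table():
    return make_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
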