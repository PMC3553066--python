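import numpy as np
import pandas as pd
import pytest

from mcopa import ExpressionMatrix


def make_matrix(values, n_normal, feature_ids=None, sample_ids=None):
    """ExpressionMatrix from a nested list / array."""
    arr = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"f{i+1}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or (
        [f"N{i+1}" for i in range(n_normal)]
        + [f"T{i+1}" for i in range(arr.shape[1] - n_normal)]
    )
    return ExpressionMatrix(
        pd.DataFrame(arr, index=feature_ids, columns=sample_ids), n_normal
    )


@pytest.fixture
def small_matrix():
    """4 features x 6 samples (2 normal), fully observed."""
    rng = np.random.default_rng(11)
    return make_matrix(rng.normal(8, 1, (4, 6)), n_normal=2)
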