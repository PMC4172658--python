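import numpy as np
import pytest

from fprf import ExpressionDataset


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 4 samples, 2 classes of 2; non-constant rows."""
    values = np.array(
        [
            [1.0, 2.0, 7.0, 8.0],
            [5.0, 6.0, 5.5, 6.5],
            [3.0, 1.0, 4.0, 2.0],
        ]
    )
    return ExpressionDataset(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        values,
        {"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
    )


def make_dataset(values, classes_per_sample, feature_prefix="g"):
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    fids = [f"{feature_prefix}{i+1}" for i in range(n_feat)]
    sids = [f"s{j+1}" for j in range(n_samp)]
    return ExpressionDataset(
        fids, sids, values, dict(zip(sids, classes_per_sample))
    )


@pytest.fixture
def make_ds():
    return make_dataset
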