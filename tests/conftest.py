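import numpy as np
import pandas as pd
import pytest

from exonet.containers import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_labeled_matrix(rng, n_features=30, n_tumor=20, n_control=10,
                        effect=0.0, n_effect=0, modality="log2"):
    """A features x samples log2 matrix with an optional planted mean shift."""
    ids = [f"T{i:03d}" for i in range(n_tumor)] + [f"N{i:03d}" for i in range(n_control)]
    X = rng.normal(8.0, 1.0, size=(n_features, n_tumor + n_control))
    X[:n_effect, :n_tumor] += effect
    matrix = ExpressionMatrix(
        pd.DataFrame(X, index=[f"f{j}" for j in range(n_features)], columns=ids),
        modality)
    meta = pd.DataFrame({"group": ["tumor"] * n_tumor + ["normal"] * n_control},
                        index=ids)
    meta.index.name = "sample_id"
    return matrix, meta
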