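import numpy as np
import pytest

from qsarflow import CompoundRecord, Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(X, y=None, names=None, ids=None, roles=None):
    """Build a Dataset from plain arrays (test helper)."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    names = names or [f"x{j + 1}" for j in range(k)]
    ids = ids or [f"c{i + 1}" for i in range(n)]
    records = []
    for i in range(n):
        kwargs = {}
        if y is not None and y[i] is not None:
            kwargs["pic50"] = float(y[i])
        records.append(
            CompoundRecord(ids[i], {nm: float(X[i, j]) for j, nm in enumerate(names)}, **kwargs)
        )
    return Dataset(records, list(names), roles)
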