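import numpy as np
import pandas as pd
import pytest

from tiestar import Dataset, FeatureSchema


def make_dataset(columns, outcome, kinds=None, id="test"):
    """Build a Dataset from name->array columns; kinds default to ordinal."""
    kinds = kinds or {}
    schema = []
    frame = {}
    for name, values in columns.items():
        values = np.asarray(values, dtype=float)
        kind = kinds.get(name, "ordinal")
        if kind == "continuous":
            levels = None
        else:
            levels = tuple(sorted(np.unique(values[~np.isnan(values)]).tolist()))
            if kind == "binary" and len(levels) != 2:
                levels = (0.0, 1.0)
            if kind == "ordinal" and len(levels) < 2:
                levels = None
        schema.append(FeatureSchema(name, kind, levels))
        frame[name] = values
    return Dataset(pd.DataFrame(frame), schema, np.asarray(outcome, dtype=int), id=id)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def duplicated_pair_dataset():
    """One predictive 3-level feature, an exact copy of it, and noise."""
    gen = np.random.default_rng(42)
    n = 1500
    a = gen.integers(0, 3, n)
    logits = -2.2 + 1.3 * a
    y = (gen.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    cols = {
        "A": a,
        "A_copy": a.copy(),
        "noise_1": gen.integers(0, 3, n),
        "noise_2": gen.integers(0, 2, n),
    }
    return make_dataset(cols, y, kinds={"noise_2": "binary"})
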