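import numpy as np
import pandas as pd
import pytest

from mddmarker import SimulationConfig


@pytest.fixture
def small_config():
    """A fast two-group configuration with the default 19-gene signature."""
    return SimulationConfig(n_genes=300, seed=123)


@pytest.fixture
def null_config():
    """No planted effects: both groups identically distributed."""
    return SimulationConfig(n_genes=2000, signature=(), seed=7)


@pytest.fixture
def marker_table():
    """A tiny continuous marker table with an obvious group split."""
    rng = np.random.default_rng(5)
    res = rng.normal(0.0, 1.0, size=(8, 2))
    nres = rng.normal(3.0, 1.0, size=(8, 2))
    values = pd.DataFrame(
        np.vstack([res, nres]),
        columns=["mA", "mB"],
        index=[f"S{i:02d}" for i in range(16)],
    )
    labels = pd.Series(["RES"] * 8 + ["NRES"] * 8, index=values.index)
    return values, labels
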