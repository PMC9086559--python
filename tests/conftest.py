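import numpy as np
import pandas as pd
import pytest

from cernaforge.expression import ExprMatrix


@pytest.fixture
def toy_counts() -> ExprMatrix:
    """3 features x 4 samples with unit-friendly library sizes."""
    df = pd.DataFrame(
        [[100, 50, 0, 10],
         [200, 100, 20, 40],
         [300, 150, 10, 20]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"])
    lib = pd.Series([1_000_000, 2_000_000, 1_000_000, 2_000_000], index=df.columns)
    lengths = pd.Series([1.0, 0.5, 2.0], index=df.index)
    return ExprMatrix(df, kind="count", lib_sizes=lib, feature_lengths_kb=lengths)


@pytest.fixture
def surv_uncensored() -> pd.DataFrame:
    rng = np.random.default_rng(11)
    n = 60
    return pd.DataFrame({
        "sample": [f"P{i}" for i in range(n)],
        "time": rng.exponential(5.0, size=n),
        "event": np.ones(n, dtype=int),
        "geneA": rng.standard_normal(n),
    })
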