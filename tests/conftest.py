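import numpy as np
import pandas as pd
import pytest

from gutweave.containers import CountTable


@pytest.fixture
def tiny_table() -> CountTable:
    """Hand-built 4-taxa × 6-sample table over two diets at one timepoint."""
    counts = pd.DataFrame(
        {
            f"s{i}": col
            for i, col in enumerate(
                [[10, 5, 0, 1], [8, 6, 1, 0], [12, 4, 0, 1],
                 [2, 9, 3, 0], [1, 11, 2, 0], [3, 10, 4, 1]]
            )
        },
        index=["taxA", "taxB", "taxC", "taxD"],
    )
    meta = pd.DataFrame(
        {
            "diet": ["control"] * 3 + ["butyrate"] * 3,
            "timepoint": [68] * 6,
            "source": ["gut"] * 6,
        },
        index=[f"s{i}" for i in range(6)],
    )
    return CountTable(counts, meta)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
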