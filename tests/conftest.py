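import numpy as np
import pandas as pd
import pytest

from fmnet import abundance as ab


@pytest.fixture
def counts_table() -> ab.AbundanceTable:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 500, size=(6, 8))
    counts[:, 0] += 2000  # one dominant taxon
    df = pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(6)],
        columns=[f"otu{j}" for j in range(8)],
    )
    return ab.AbundanceTable(df, kind="counts")


@pytest.fixture
def relative_table(counts_table) -> ab.AbundanceTable:
    return ab.to_relative(counts_table)


def make_relative(rows, index=None, columns=None) -> ab.AbundanceTable:
    arr = np.asarray(rows, dtype=float)
    df = pd.DataFrame(
        arr,
        index=index or [f"s{i}" for i in range(arr.shape[0])],
        columns=columns or [f"t{j}" for j in range(arr.shape[1])],
    )
    return ab.AbundanceTable(df, kind="relative")
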