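"""Shared helpers: seed handling and delimited-table I/O."""

from __future__ import annotations

import numpy as np
import pandas as pd

#: float formatting used by every writer so that reruns are byte-identical
FLOAT_FORMAT = "%.10g"


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed.

    Independent streams per output block mean that adding a new consumer of
    randomness never perturbs the draws of existing ones.
    """
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def write_table(df: pd.DataFrame, path, header_comments: list[str] | None = None) -> None:
    """Write a DataFrame as TSV/CSV with optional ``#key=value`` header lines."""
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"#{line}\n")
        df.to_csv(fh, sep=sep_for(path), float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep_for(path), index_col=0, comment="#")
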