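from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirsig.toptable_io import DETable, from_frame


def make_table(rows, dataset_id="T", disease="D") -> DETable:
    """Build a DETable from (symbol, log2fc, fdr[, pvalue]) tuples."""
    records = []
    for row in rows:
        symbol, log2fc, fdr = row[0], row[1], row[2]
        pvalue = row[3] if len(row) > 3 else fdr
        records.append(
            {"symbol": symbol, "log2fc": log2fc, "fdr": fdr, "pvalue": pvalue}
        )
    return from_frame(pd.DataFrame(records), dataset_id, disease)


def random_table(rng: np.random.Generator, n_genes: int, dataset_id: str,
                 disease: str = "D") -> DETable:
    """A random but internally valid top-table for property checks."""
    symbols = [f"G{i:04d}" for i in range(n_genes)]
    return from_frame(
        pd.DataFrame(
            {
                "symbol": symbols,
                "log2fc": rng.normal(0, 2, n_genes),
                "fdr": rng.uniform(0, 1, n_genes) ** 2,
            }
        ),
        dataset_id,
        disease,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
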