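import numpy as np
import pandas as pd
import pytest

from dualreg.io import DETable


@pytest.fixture
def make_de_table():
    """Factory: build a DETable from parallel per-gene value lists."""

    def _make(contrast_id, genes, log2fc, adj_p=None, p_value=None):
        n = len(genes)
        data = pd.DataFrame(
            {
                "log2fc": np.asarray(log2fc, dtype=float),
                "p_value": np.asarray(p_value if p_value is not None else [0.01] * n,
                                      dtype=float),
                "adj_p": np.asarray(adj_p if adj_p is not None else [0.01] * n,
                                    dtype=float),
            },
            index=pd.Index(genes, name="gene"),
        )
        return DETable(contrast_id=contrast_id, data=data)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
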