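import numpy as np
import pandas as pd
import pytest

from cci_delta import AnnotatedExpression, LRDatabase, LRPair


@pytest.fixture
def toy_db() -> LRDatabase:
    """Two directed pairs and one undirected pair with private genes."""
    return LRDatabase(
        [
            LRPair("CPI-A", "L1", "R1", a_is_receptor=False, b_is_receptor=True),
            LRPair("CPI-B", "L2", "R2", a_is_receptor=False, b_is_receptor=True),
            LRPair("CPI-U", "M1", "M2", a_is_receptor=False, b_is_receptor=False),
        ]
    )


@pytest.fixture
def toy_expression() -> AnnotatedExpression:
    """Deterministic 6-cell, 2-type matrix over 5 genes."""
    rng = np.random.default_rng(42)
    genes = ["L1", "R1", "L2", "R2", "M1", "M2"]
    values = rng.uniform(0.1, 3.0, size=(6, len(genes)))
    cells = [f"c{i}" for i in range(6)]
    labels = ["A", "A", "A", "B", "B", "B"]
    return AnnotatedExpression(
        values=values,
        cell_ids=pd.Index(cells),
        gene_ids=pd.Index(genes),
        cell_type=pd.Series(labels, index=cells),
    )
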