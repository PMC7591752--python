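import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from spongenet.io_core import ExpressionMatrix
from spongenet.synthetic_data import PRESETS, generate


def make_expr(mat, gene_class="mRNA", gene_ids=None, groups=None):
    """Small helper: wrap a 2-D array as an ExpressionMatrix."""
    mat = np.asarray(mat, dtype=float)
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(mat.shape[0])]
    cols = [f"s{i:03d}" for i in range(mat.shape[1])]
    if groups is None:
        half = mat.shape[1] // 2
        groups = ["case"] * half + ["control"] * (mat.shape[1] - half)
    labels = dict(zip(cols, groups))
    return ExpressionMatrix(pd.DataFrame(mat, index=gene_ids, columns=cols),
                            gene_class, labels)


@pytest.fixture(scope="session")
def small_dataset():
    """The small synthetic preset, generated once per test session."""
    return generate(PRESETS["small"], seed=1)
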