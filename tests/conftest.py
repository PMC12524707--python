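import numpy as np
import pandas as pd
import pytest

from gmtrepurpose.core_io import ExpressionMatrix


def make_expr(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"S{i + 1}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def two_block_expr(n_per=50, within=0.8, n_samples=60, n_bg=0, seed=0) -> ExpressionMatrix:
    """Two independent co-expressed blocks with the given within-block correlation."""
    rng = np.random.default_rng(seed)
    lam = np.sqrt(within / (1 - within))
    blocks, names = [], []
    for b in range(2):
        f = rng.standard_normal(n_samples)
        blocks.append(lam * f + rng.standard_normal((n_per, n_samples)))
        names += [f"B{b}_{i:03d}" for i in range(n_per)]
    if n_bg:
        blocks.append(rng.standard_normal((n_bg, n_samples)))
        names += [f"BG_{i:03d}" for i in range(n_bg)]
    return ExpressionMatrix(
        pd.DataFrame(np.vstack(blocks), index=names,
                     columns=[f"S{i}" for i in range(n_samples)])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_expr():
    """4 genes x 2 samples, strictly decreasing in sample 1."""
    return make_expr([[4.0, 1.0], [3.0, 2.0], [2.0, 3.0], [1.0, 4.0]])
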