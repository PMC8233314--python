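import numpy as np
import pandas as pd
import pytest

from astrodiverge.io_formats import ExpressionTable, OrthologTable


@pytest.fixture
def small_expression():
    """3 genes x 4 samples, two species, raw counts."""
    values = pd.DataFrame(
        {"h1": [10.0, 0.0, 5.0], "h2": [12.0, 1.0, 4.0],
         "m1": [8.0, 2.0, 6.0], "m2": [9.0, 0.0, 7.0]},
        index=["gA", "gB", "gC"],
    )
    meta = pd.DataFrame(
        {"species": ["human", "human", "mouse", "mouse"],
         "condition": ["acute"] * 4},
        index=["h1", "h2", "m1", "m2"],
    )
    return ExpressionTable(values, meta)


@pytest.fixture
def identity_orthologs():
    def make(genes):
        return OrthologTable(pd.DataFrame({"human": list(genes), "mouse": list(genes)}))
    return make


@pytest.fixture
def block_expression():
    """Planted 4 correlated blocks of 100 genes plus 200 noise genes, 48 samples."""
    def make(seed=0, n_samp=48, nblocks=4, bsize=100, noise=200, r=0.7):
        rng = np.random.default_rng(seed)
        rows, truth = [], []
        for b in range(nblocks):
            f = rng.normal(size=n_samp)
            for _ in range(bsize):
                rows.append(np.sqrt(r) * f + np.sqrt(1 - r) * rng.normal(size=n_samp))
                truth.append(b + 1)
        for _ in range(noise):
            rows.append(rng.normal(size=n_samp))
            truth.append(0)
        X = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
        return X, np.array(truth)
    return make
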