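import numpy as np
import pandas as pd
import pytest

import trajdiff as td


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(n_genes=3, n_cells_per_sample=(3, 3), seed=0):
    """Tiny deterministic in-memory dataset for I/O and plumbing tests."""
    rng = np.random.default_rng(seed)
    S = len(n_cells_per_sample)
    samples = [f"s{j}" for j in range(S)]
    cells, samp = [], []
    for j, c in enumerate(n_cells_per_sample):
        cells += [f"s{j}_c{i}" for i in range(c)]
        samp += [samples[j]] * c
    n = len(cells)
    expr = rng.normal(1.0, 0.5, (n_genes, n))
    return td.MultiSampleDataset(
        expression=expr,
        gene_ids=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        cell_ids=np.array(cells, dtype=object),
        sample_of_cell=np.array(samp, dtype=object),
        embedding=rng.normal(0, 1, (n, 2)),
        sample_design=pd.DataFrame(
            {"intercept": 1.0,
             "group": [float(j >= S / 2) for j in range(S)]},
            index=samples),
    )


@pytest.fixture
def tiny_dataset():
    return make_dataset()


@pytest.fixture(scope="session")
def sim_obs():
    """A moderately sized draw from the generative model (one gene)."""
    rng = np.random.default_rng(7)
    S, K = 10, 3
    basis = td.make_basis(K)
    B = rng.normal(0, 1, (K + 1, 2))
    x = np.c_[np.ones(S), np.r_[np.zeros(5), np.ones(5)]]
    ys, ts = [], []
    for s in range(S):
        C = 200
        t = rng.uniform(0, 1, C)
        sig2 = 1 / rng.gamma(3.0, 1 / 2.0)
        u = rng.normal(0, np.sqrt(sig2 * 0.09), K + 1)
        ys.append(basis(t) @ (B @ x[s] + u) + rng.normal(0, np.sqrt(sig2), C))
        ts.append(t)
    obs = td.GeneObservations(ys, ts, [f"s{j}" for j in range(S)])
    return obs, x, B, K
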