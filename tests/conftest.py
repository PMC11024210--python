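import numpy as np
import pytest

from qglia.simulate import SimConfig, generate_counts


@pytest.fixture(scope="session")
def small_planted():
    """300 cells, 3 well-separated planted clusters; (adata, truth)."""
    cfg = SimConfig(n_cells=300, n_genes=600, n_clusters=3, n_markers_per_cluster=20, seed=42)
    return generate_counts(cfg)


@pytest.fixture(scope="session")
def blobs():
    """Two Gaussian blobs 10 SD apart with labels.

    For graph methods use k comparable to the blob size (e.g. 40): a kNN
    graph of a diffuse blob at small k is a geometric graph with genuine
    internal community structure, which is not the separation this
    fixture is meant to probe."""
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, size=(60, 5))
    b = rng.normal(10, 1, size=(60, 5))
    X = np.vstack([a, b])
    y = np.array([0] * 60 + [1] * 60)
    return X, y
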