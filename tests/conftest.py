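import numpy as np
import pytest

from scalemap import RegimeConfig, SpatialDataset, generate_regime, normalize_counts


@pytest.fixture(scope="session")
def circle_samples():
    """Three small circle-regime samples sharing one count model."""
    cfg = RegimeConfig(regime="circle", n_samples=3, n_cells=300, n_genes=80, seed=7)
    return generate_regime(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_dataset(
    n_genes=5,
    n_cells=6,
    seed=0,
    with_labels=False,
    normalized=False,
    sample_id="toy",
):
    """Small random dataset with distinct cell profiles."""
    r = np.random.default_rng(seed)
    counts = r.poisson(5.0, size=(n_genes, n_cells)) + 1  # no all-zero cells
    coords = r.uniform(0, 1, size=(n_cells, 2))
    labels = None
    if with_labels:
        labels = np.array([f"type_{i % 3}" for i in range(n_cells)], dtype=object)
    d = SpatialDataset(
        sample_id=sample_id,
        barcodes=[f"{sample_id}_c{i}" for i in range(n_cells)],
        coords=coords,
        counts=counts,
        genes=[f"g{i}" for i in range(n_genes)],
        cell_labels=labels,
    )
    if normalized:
        d = normalize_counts(d)
    return d


@pytest.fixture()
def toy_dataset():
    return make_dataset()
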