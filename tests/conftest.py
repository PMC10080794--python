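import numpy as np
import pandas as pd
import pytest

from mzt_m6a import OmicsDataset, SimConfig, simulate_counts, simulate_truth


@pytest.fixture
def toy_dataset() -> OmicsDataset:
    """3 genes x one stage of paired IP/input triplicates, tiny counts."""
    genes = ["gA", "gB", "gC"]
    cols = {}
    rng = np.random.default_rng(0)
    for rep in (1, 2, 3):
        cols[f"MII_input_{rep}"] = rng.poisson(50, 3)
        cols[f"MII_IP_{rep}"] = rng.poisson(50, 3)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame(
        {
            "sample_id": list(cols),
            "stage": ["MII"] * 6,
            "assay": ["input", "IP"] * 3,
            "replicate": [1, 1, 2, 2, 3, 3],
        }
    )
    lengths = pd.Series([1000.0, 1500.0, 2000.0], index=genes)
    return OmicsDataset(counts=counts, samples=samples, gene_lengths=lengths)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic dataset (600 genes) shared by tests."""
    cfg = SimConfig(n_genes=600, library_size=2e5, seed=1)
    truth = simulate_truth(cfg)
    dataset = simulate_counts(truth, cfg)
    return cfg, truth, dataset
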