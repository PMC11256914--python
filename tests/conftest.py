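import numpy as np
import pytest

from phylaugment.otu_io import OtuTable, TaxonomyMap
from phylaugment.synth_data import SimConfig, simulate_dataset


@pytest.fixture
def small_table() -> OtuTable:
    """4 samples x 3 OTUs with labels; relative mode."""
    values = np.array([
        [0.5, 0.5, 0.0],
        [0.2, 0.3, 0.5],
        [1.0, 0.0, 0.0],
        [0.1, 0.1, 0.8],
    ])
    return OtuTable(values=values, sample_ids=["s1", "s2", "s3", "s4"],
                    otu_ids=["g1", "g2", "g3"], labels=np.array([0, 0, 1, 1]),
                    mode="relative")


@pytest.fixture
def count_table() -> OtuTable:
    values = np.array([[2, 2, 0, 4], [1, 0, 0, 3], [5, 5, 5, 5]], dtype=float)
    return OtuTable(values=values, sample_ids=["a", "b", "c"],
                    otu_ids=["o1", "o2", "o3", "o4"], mode="counts")


@pytest.fixture(scope="session")
def sim_small():
    """Small simulated cohort shared across tests (120 samples, 60 OTUs)."""
    cfg = SimConfig(
        n_cases=60, n_controls=60, n_otus=60,
        phyla=[("Firmicutes", 25), ("Proteobacteria", 20), ("Actinobacteria", 15)],
        n_differential=15, effect_log2fc=3.0, seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def taxonomy_small() -> TaxonomyMap:
    entries = {
        f"g{i}": {"kingdom": "Bacteria",
                  "phylum": ["Firmicutes", "Proteobacteria"][i % 2],
                  "genus": f"genus{i}"}
        for i in range(6)
    }
    return TaxonomyMap(entries=entries)
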