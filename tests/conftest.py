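import numpy as np
import pandas as pd
import pytest

import milkbiome as mb
from milkbiome.synthetic import SPIKE_FEATURE


@pytest.fixture
def tiny_table():
    """3 features x 3 samples, one spiked NTC."""
    counts = pd.DataFrame(
        {"S1": [5, 1, 0], "S2": [0, 1, 2], "N1": [0, 0, 10]},
        index=["OTU_1", "OTU_2", "OTU_C"],
    )
    return mb.CountTable(counts, {"N1": "ntc_spiked"})


@pytest.fixture
def taxonomy():
    return mb.TaxonomyMap({
        "OTU_1": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                  "Streptococcaceae", "Streptococcus"),
        "OTU_2": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                  "Streptococcaceae", "Streptococcus"),
        "OTU_C": ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                  "Enterobacteriales", "Enterobacteriaceae", None),
    })


@pytest.fixture
def cohort():
    """A small study-like cohort with moderate contamination (seeded)."""
    spec = mb.default_spec(
        n_per_cluster={"cluster_1": 12, "cluster_2": 12, "cluster_3": 12},
        contamination_fraction=0.05,
        seed=42,
    )
    return mb.generate_cohort(spec)


@pytest.fixture
def spike_id():
    return SPIKE_FEATURE


def random_count_table(rng, n_features=8, n_samples=5, max_count=50):
    counts = pd.DataFrame(
        rng.integers(0, max_count, size=(n_features, n_samples)),
        index=[f"OTU_{i}" for i in range(n_features)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
    # ensure no zero-total column
    for j in range(n_samples):
        if counts.iloc[:, j].sum() == 0:
            counts.iloc[0, j] = 1
    return mb.CountTable(counts)
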