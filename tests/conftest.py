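import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ruminet import SimConfig, simulate_pair
from ruminet.enrich import GeneSetCollection

SMALL_CLUSTERS = {
    "muscle": 24,
    "muscle_junction": 12,
    "cell_cycle": 15,
    "epithelial_diff": 15,
    "general_metab": 24,
    "lipid_oxo": 15,
}


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A 300-gene scaled-down configuration for fast unit tests."""
    kwargs = dict(n_genes=300, cluster_sizes=dict(SMALL_CLUSTERS), seed=seed)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def default_sim():
    """One realization of the full default study conditions (1000 genes,
    62 + 24 samples)."""
    return simulate_pair(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    return simulate_pair(small_sim_config(seed=0))


@pytest.fixture()
def truth_markers(default_sim):
    truth = default_sim[4]
    return GeneSetCollection(
        sets={
            label: truth.members(label)
            for label in (
                "muscle", "muscle_junction", "cell_cycle",
                "epithelial_diff", "general_metab", "lipid_oxo",
            )
        },
        source="synthetic-truth",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def write_counts_tsv(path, gene_ids, sample_ids, counts):
    df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    df.to_csv(path, sep="\t", index_label="gene_id")
    return path
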