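import numpy as np
import pytest

from cladecompare.synthetic import CladeConfig, simulate_clade, simulate_hit_table, DEFAULT_TAXONOMY


@pytest.fixture(scope="session")
def small_clade_config():
    """Six-taxon clade scaled down for unit-test speed."""
    return CladeConfig(
        genome_length=60_000,
        n_gene_families=50,
        mean_gene_len=600,
        hgt_rate=20.0,
        is_element=(800, {"BP1": 6, "NIES2134": 6}),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_clade(small_clade_config):
    return simulate_clade(small_clade_config)


@pytest.fixture(scope="session")
def focal_hits(small_clade):
    _, truth, _ = small_clade
    return simulate_hit_table(truth, DEFAULT_TAXONOMY, "Thermosynechococcus", seed=3,
                              genomes=["CL1"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
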