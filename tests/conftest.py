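import numpy as np
import pandas as pd
import pytest

from straincgh.simulate import SimulationConfig, simulate_cohort

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort():
    """The full default synthetic cohort: 22 strains in groups 7/13/1/1,
    16 chromosomes x 300 genes, |delta_log2| = 1.0, noise_sd = 0.15,
    reference_bias_sd = 0.3, fixed seed."""
    return simulate_cohort(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down config for fast plumbing tests: 4 chromosomes x 40
    genes, 10 subtelomeric genes per chromosome end."""
    return SimulationConfig(
        seed=11,
        n_chromosomes=4,
        genes_per_chromosome=40,
        chromosome_length_bp=120_000,
        group_sizes=(3, 4, 1),
        n_terms=5,
        genes_per_term=8,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def tiny_annotation():
    """Five genes on two chromosomes, genome order g1..g5."""
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4", "g5"],
            "chromosome": [1, 1, 1, 2, 2],
            "start": [1, 101, 201, 1, 101],
            "end": [100, 200, 300, 100, 200],
            "subtelomeric": [1, 0, 1, 1, 1],
        }
    )


def random_matrix(rng, n_genes=8, n_strains=4, nan_frac=0.0):
    values = rng.normal(size=(n_genes, n_strains))
    if nan_frac:
        mask = rng.random(values.shape) < nan_frac
        values[mask] = np.nan
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_strains)],
    )
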