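import numpy as np
import pandas as pd
import pytest

from agingaccel.synth import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Small planted cohort shared across tests (read-only)."""
    cfg = SyntheticConfig(
        n_tissues=4,
        samples_per_tissue=30,
        n_cpgs=500,
        n_aging_cpgs=20,
        aging_effect=0.3,
        n_genes=300,
        n_mutation_genes=60,
        n_driver_mutations=2,
        module_size=6,
        module_effect=2.0,
        noise_sd=0.05,
        seed=11,
    )
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with every effect size zero: nothing is age- or mutation-associated."""
    cfg = SyntheticConfig(
        n_tissues=2,
        samples_per_tissue=20,
        n_cpgs=300,
        n_aging_cpgs=0,
        aging_effect=0.0,
        n_genes=100,
        n_mutation_genes=30,
        n_driver_mutations=0,
        driver_accel_effect=0.0,
        module_size=0,
        module_effect=0.0,
        noise_sd=0.05,
        seed=5,
    )
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def paired_frames(cohort):
    """(tumor, normal, mutation_status) aligned by pair id, plus annotations."""
    ann = cohort.annotations
    t_ids = ann.index[ann["status"] == "tumor"]
    n_ids = ann.index[ann["status"] == "normal"]
    pairs = ann.loc[t_ids, "pair_id"].to_numpy()
    tumor = cohort.expression.loc[t_ids].set_axis(pairs, axis=0)
    normal = (
        cohort.expression.loc[n_ids]
        .set_axis(ann.loc[n_ids, "pair_id"].to_numpy(), axis=0)
        .loc[pairs]
    )
    status = cohort.mutation.loc[t_ids].set_axis(pairs, axis=0)
    return tumor, normal, status
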