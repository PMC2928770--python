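import warnings

import numpy as np
import pandas as pd
import pytest

import refstab as rs


@pytest.fixture(scope="session")
def default_study():
    """One default-configuration synthetic study, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cq, meta, truth = rs.generate(rs.default_config(), seed=11)
    return cq, meta, truth


@pytest.fixture(scope="session")
def default_agg(default_study):
    cq, _, _ = default_study
    return rs.aggregate_technical_replicates(cq)


@pytest.fixture(scope="session")
def default_datasets(default_study):
    _, meta, _ = default_study
    return rs.partition_datasets(meta)


def random_quantities(rng, n_genes=5, n_samples=10):
    """A positive random genes x samples quantity matrix."""
    q = pd.DataFrame(
        2.0 ** rng.normal(0.0, 1.0, (n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    q.index.name = "gene"
    q.columns.name = "sample_id"
    return q
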