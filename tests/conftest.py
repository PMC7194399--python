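import numpy as np
import pandas as pd
import pytest

from microcca import (
    OtuTable,
    fit_cca,
    pareto_scale,
    prevalence_partition,
    select_components,
    total_sum_scale,
)
from microcca.synthetic import SyntheticScenario, generate


@pytest.fixture
def tiny_counts() -> pd.DataFrame:
    """3 OTUs x 2 samples with column sums [10, 10]."""
    return pd.DataFrame(
        [[2, 0], [3, 1], [5, 9]],
        index=["otu_1", "otu_2", "otu_3"],
        columns=["s1", "s2"],
    )


@pytest.fixture
def tiny_table(tiny_counts) -> OtuTable:
    return OtuTable(counts=tiny_counts.copy())


@pytest.fixture(scope="session")
def synth_data():
    """One default synthetic dataset, shared across tests."""
    return generate(SyntheticScenario(seed=42))


@pytest.fixture(scope="session")
def fitted(synth_data):
    """Preprocessed matrices, fitted model and selection for the shared dataset."""
    abund = total_sum_scale(synth_data.otu_table)
    part = prevalence_partition(abund)
    scaled = pareto_scale(abund, part.ubiquitous)
    model = fit_cca(scaled, n_components=2)
    selection = select_components(model)
    return {
        "abund": abund,
        "part": part,
        "scaled": scaled,
        "model": model,
        "selection": selection,
    }


def random_counts(rng, n_otus, n_samples, sparsity=0.6, max_count=500) -> pd.DataFrame:
    """A random valid count table: integer counts with controlled sparsity."""
    counts = rng.integers(1, max_count, size=(n_otus, n_samples))
    mask = rng.random((n_otus, n_samples)) < sparsity
    counts = np.where(mask, 0, counts)
    # keep every sample total positive
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[rng.integers(n_otus), j] = 1
    return pd.DataFrame(
        counts,
        index=[f"otu_{i}" for i in range(n_otus)],
        columns=[f"s_{j}" for j in range(n_samples)],
    )
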