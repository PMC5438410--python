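import numpy as np
import pandas as pd
import pytest

from pnetquant import synthetic_data as sd
from pnetquant.tabular_io import SpectralCountMatrix


def make_matrix(counts: dict, lengths, unique_peptides=None, meta=None):
    """Construct a small validated SpectralCountMatrix from plain dicts."""
    counts_df = pd.DataFrame(counts)
    counts_df.index.name = "protein_id"
    n = len(counts_df)
    lengths = pd.Series(lengths, index=counts_df.index, name="length_aa")
    if unique_peptides is None:
        unique_peptides = [3] * n
    up = pd.Series(unique_peptides, index=counts_df.index,
                   name="unique_peptides")
    if meta is None:
        samples = list(counts_df.columns)
        meta = pd.DataFrame({
            "condition": ["tumor" if s.startswith("T") else "para_tumor"
                          for s in samples],
            "pair_id": [s[1:] for s in samples],
        }, index=pd.Index(samples, name="sample"))
    return SpectralCountMatrix(counts=counts_df, lengths=lengths,
                               unique_peptides=up, sample_meta=meta)


@pytest.fixture
def two_protein_matrix():
    """Proteins A(S=4, L=2) and B(S=1, L=1) in one sample pair."""
    return make_matrix(
        {"T1": [4, 1], "N1": [2, 2], "T2": [4, 1], "N2": [2, 2]},
        lengths=[2, 1])


@pytest.fixture
def paired_matrix_4x4():
    """Four tumor/para-tumor pairs over three proteins."""
    rng = np.random.default_rng(0)
    counts = {}
    for j in range(1, 5):
        counts[f"T{j}"] = rng.poisson([40, 10, 5])
        counts[f"N{j}"] = rng.poisson([10, 10, 5])
    m = make_matrix(counts, lengths=[300, 200, 150])
    return m


@pytest.fixture(scope="session")
def default_experiment():
    """One study-scale simulated spectral experiment (shared, read-only)."""
    return sd.simulate_spectral_experiment(sd.SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def default_cohort():
    return sd.simulate_cohort(sd.SimulationSpec(seed=7))
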