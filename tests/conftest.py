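import networkx as nx
import numpy as np
import pandas as pd
import pytest

from proxikit.containers import AbundanceMatrix, PeptideIntensityTable


def make_matrix(values, conditions, donors=None, batches=None, peptides=None):
    """Build a small AbundanceMatrix from a protein->values dict.

    ``conditions`` gives one label per sample column; donor/batch default to
    one donor per column and a single batch.
    """
    proteins = list(values)
    n_samples = len(conditions)
    donors = donors or [f"D{i + 1:02d}" for i in range(n_samples)]
    batches = batches or ["B1"] * n_samples
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    intensities = pd.DataFrame(
        np.array([values[p] for p in proteins], dtype=float),
        index=proteins, columns=sample_ids,
    )
    meta = pd.DataFrame(
        {"donor": donors, "condition": conditions, "batch": batches},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if peptides is None:
        peptides = {p: 3 for p in proteins}
    up = pd.Series([peptides[p] for p in proteins], index=proteins,
                   name="unique_peptides")
    return AbundanceMatrix(intensities, meta, up)


def make_peptide_table(rows):
    """rows: iterable of (peptide, protein, donor, condition, intensity, is_heavy)."""
    return PeptideIntensityTable(pd.DataFrame(
        rows,
        columns=["peptide", "protein", "donor", "condition", "intensity", "is_heavy"],
    ))


@pytest.fixture
def path5():
    """Path graph a-b-c-d-e."""
    g = nx.Graph()
    nx.add_path(g, list("abcde"))
    return g


@pytest.fixture(scope="session")
def ba_network():
    """A 500-node scale-free network shared by the heavier statistical tests."""
    from proxikit.synthetic_data import generate_network

    return generate_network(500, 3, seed=42)
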