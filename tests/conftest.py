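import numpy as np
import pandas as pd
import pytest

import spliceome as sp


@pytest.fixture
def toy_gene():
    """One gene, 3 transcripts x 4 samples with known dominance structure.

    Per-sample totals are all 10, so usage rows are TPM/10.
    """
    matrix = pd.DataFrame(
        [[8, 4, 6, 2], [1, 5.5, 3, 7], [1, 0.5, 1, 1]],
        index=pd.Index(["T1", "T2", "T3"], name="transcript_id"),
        columns=["S1", "S2", "S3", "S4"],
        dtype=float,
    )
    annotation = pd.DataFrame(
        {
            "gene_id": ["G1"] * 3,
            "gene_symbol": ["GENE1"] * 3,
            "biotype": ["protein_coding", "protein_coding", "retained_intron"],
            "protein_length_aa": [190.0, 150.0, np.nan],
        },
        index=matrix.index,
    )
    return matrix, annotation


@pytest.fixture
def random_fixture():
    """Seeded 20-gene x 30-sample matrix with multi-isoform genes."""
    rng = np.random.default_rng(42)
    genes, tx, biotypes = [], [], []
    classes = ["protein_coding", "nonsense_mediated_decay", "retained_intron", "other"]
    for g in range(20):
        k = int(rng.integers(1, 5))
        for j in range(k):
            genes.append(f"G{g:02d}")
            tx.append(f"G{g:02d}T{j}")
            biotypes.append(classes[0] if j == 0 else classes[int(rng.integers(0, 4))])
    values = rng.gamma(shape=1.2, scale=8.0, size=(len(tx), 30))
    values[rng.random(values.shape) < 0.15] = 0.0  # sparse zeros, incl. whole genes
    matrix = pd.DataFrame(
        values, index=pd.Index(tx, name="transcript_id"), columns=[f"S{i:02d}" for i in range(30)]
    )
    annotation = pd.DataFrame(
        {
            "gene_id": genes,
            "gene_symbol": [f"SYM{g[1:]}" for g in genes],
            "biotype": biotypes,
            "protein_length_aa": np.nan,
        },
        index=matrix.index,
    )
    samples = pd.DataFrame(
        {
            "subject_id": [f"SUBJ{i % 10}" for i in range(30)],
            "tissue": [["blood", "brain", "liver"][i % 3] for i in range(30)],
            "sex": [["female", "male"][i % 2] for i in range(30)],
            "age_bracket": "40-49",
            "library_prep": [["polyA", "total"][i % 2] for i in range(30)],
            "project_id": "P1",
            "condition": "control",
        },
        index=matrix.columns,
    )
    return matrix, annotation, samples


@pytest.fixture
def small_cohort():
    """Default-config simulated cohort, single seed, reused across tests."""
    return sp.simulate_cohort(sp.SimulationConfig(seed=11))
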