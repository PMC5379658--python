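import numpy as np
import pandas as pd
import pytest

from tnbc_concord.data_model import (
    CentroidSet,
    ExpressionMatrix,
    GeneAnnotation,
    PairedDesign,
)
from tnbc_concord.synthetic_data import SimConfig, generate


@pytest.fixture
def tiny_counts() -> ExpressionMatrix:
    data = pd.DataFrame(
        {"S1": [10.0, 90.0, 0.0], "S2": [5.0, 45.0, 50.0]},
        index=["G1", "G2", "G3"],
    )
    return ExpressionMatrix(data, "count")


@pytest.fixture
def tiny_annotation() -> GeneAnnotation:
    table = pd.DataFrame(
        {
            "transcript_class": ["protein_coding", "protein_coding", "rRNA"],
            "transcript_length": [500, 4500, 1000],
        },
        index=pd.Index(["G1", "G2", "G3"], name="gene_id"),
    )
    return GeneAnnotation(table)


@pytest.fixture
def toy_centroids() -> CentroidSet:
    # two profiles over six genes: B is the reverse of A
    data = pd.DataFrame(
        {"A": [2.0, 1.0, 3.0, 4.0, 6.0, 5.0], "B": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]},
        index=[f"G{i}" for i in range(1, 7)],
    )
    return CentroidSet(data)


@pytest.fixture
def simple_design() -> PairedDesign:
    return PairedDesign(
        pd.DataFrame(
            {
                "sample_a": ["P1_FF", "P2_FF", "P3_FF"],
                "sample_b": ["P1_FFPE", "P2_FFPE", "P3_FFPE"],
                "platform": "hiseq_like",
                "age_class": "new_lt4y",
            },
            index=pd.Index(["P1", "P2", "P3"], name="pair_id"),
        )
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration cohort shared across tests (seed 1)."""
    return generate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A smaller, faster cohort for pipeline-level tests."""
    return generate(SimConfig(seed=3, n_genes=1200, n_pairs=8, n_exon_genes=10))
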