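import numpy as np
import pandas as pd
import pytest

from snoclass.data import AbundanceMatrix
from snoclass.simulate import SimulationParams, simulate_cohort


@pytest.fixture
def small_matrix() -> AbundanceMatrix:
    """3 genes x 6 samples over two tissues."""
    values = pd.DataFrame(
        {
            "brain_1": [2.0, 10.0, 0.0],
            "brain_2": [4.0, 12.0, 0.0],
            "brain_3": [6.0, 11.0, 0.0],
            "liver_1": [1.0, 50.0, 0.0],
            "liver_2": [2.0, 55.0, 0.0],
            "liver_3": [3.0, 45.0, 0.0],
        },
        index=["G1", "G2", "G3"],
    )
    tissues = pd.Series(
        ["brain"] * 3 + ["liver"] * 3,
        index=values.columns, name="tissue")
    return AbundanceMatrix(values, tissues)


@pytest.fixture
def small_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_name": ["SNORD1", "HOSTG", "SCARNA5"],
            "biotype_raw": ["snoRNA", "protein_coding", "snoRNA"],
            "biotype_group": ["snoRNA", "protein-coding", "snoRNA"],
            "genomic_context": ["intronic", "intergenic", "intergenic"],
            "host_gene_id": ["G2", "", ""],
            "host_biotype_group": ["protein-coding", "intergenic", "intergenic"],
            "host_function_group": ["ribosomal protein", "", ""],
            "box_type": ["CD", "NA", "HACA"],
            "target_class": ["rRNA", "NA", "orphan"],
        },
        index=pd.Index(["G1", "G2", "G3"], name="gene_id"),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 0)."""
    return simulate_cohort(SimulationParams(seed=0))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_cohort):
    """The default cohort written to disk as TSV files."""
    from snoclass.simulate import write_fixture

    d = tmp_path_factory.mktemp("cohort")
    write_fixture(default_cohort, d)
    return d


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
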