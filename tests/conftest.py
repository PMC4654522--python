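import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from itraqpipe import (
    SampleDesign,
    compute_sample_ratios,
    default_study_design,
    filter_by_fdr,
)
from itraqpipe.quant_io import ProteinQuantRecord
from itraqpipe.synthetic_data import generate_pathway_db, generate_study


@pytest.fixture(scope="session")
def design() -> SampleDesign:
    return default_study_design()


def make_record(
    accession: str,
    group_id: int = 1,
    i113: float = 1000.0,
    i114: float = 1000.0,
    i115: float = 1000.0,
    i116: float = 1000.0,
    protein_fdr: float = 0.01,
    peptide_fdr: float = 0.01,
    n_peptides: int = 3,
    gene_model: str | None = None,
) -> ProteinQuantRecord:
    return ProteinQuantRecord(
        accession=accession,
        gene_model=gene_model or accession.lower(),
        group_id=group_id,
        channel_intensity={"113": i113, "114": i114, "115": i115, "116": i116},
        protein_fdr=protein_fdr,
        peptide_fdr=peptide_fdr,
        n_peptides=n_peptides,
    )


@pytest.fixture(scope="session")
def planted_study(design):
    """A small study with every kind of planted feature, plus its truth."""
    records, truth = generate_study(
        design,
        n_proteins=400,
        de_counts={"N2/N1": (20, 25), "N5/N4": (15, 10)},
        candidate_counts={"pericarp": 4, "endosperm": 8, "cross": 3},
        stage_specific={("pericarp", 20): 5, ("endosperm", 33): 4},
        tissue_specific={"pericarp": 6},
        noise_sd=0.05,
        seed=11,
    )
    return records, truth


@pytest.fixture(scope="session")
def planted_matrix(design, planted_study):
    records, _ = planted_study
    return compute_sample_ratios(filter_by_fdr(records), design)


@pytest.fixture(scope="session")
def toy_db():
    return generate_pathway_db(n_pathways=4, n_kos=12, edge_density=0.3, seed=5)
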