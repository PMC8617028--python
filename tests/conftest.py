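import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tme_atlas.io_formats import CountMatrix
from tme_atlas.synthetic_data import CohortDesign, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    design = CohortDesign(seed=11)
    cm, truth = generate_cohort(design)
    return cm, truth


@pytest.fixture
def small_matrix():
    """A hand-sized CountMatrix: 4 cells x 5 genes, one mito gene."""
    counts = sp.csr_matrix(
        np.array(
            [
                [3, 0, 1, 0, 1],
                [0, 5, 2, 1, 0],
                [0, 0, 0, 0, 0],
                [2, 2, 2, 2, 2],
            ]
        )
    )
    cell_ids = np.array(["c1", "c2", "c3", "c4"], dtype=object)
    gene_ids = np.array(["gA", "gB", "gC", "gD", "mito1"], dtype=object)
    gene_meta = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2", "chr2", "chrMT"],
            "start": [100, 300, 100, 500, 10],
            "end": [200, 400, 200, 600, 110],
            "strand": ["+", "-", "+", "+", "+"],
            "is_mito": [False, False, False, False, True],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    cell_meta = pd.DataFrame(
        {"patient": ["P1", "P1", "P2", "P2"]},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CountMatrix(counts, cell_ids, gene_ids, cell_meta, gene_meta)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
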