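import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import embryosex as ex


@pytest.fixture(scope="session")
def small_config():
    return ex.SimConfig(n_genes=400, n_stages=3, cells_per_stage_per_sex=15,
                        n_sexdeg_per_stage=8, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(counts, metadata, annotation, truth) for a 400-gene, 90-cell dataset."""
    return ex.simulate_counts(small_config)


@pytest.fixture(scope="session")
def sexed_dataset(small_dataset, small_config):
    counts, metadata, annotation, truth = small_dataset
    md = ex.sex_dataset(counts, metadata,
                        marker_x_id=small_config.marker_ids[0],
                        marker_y_id=small_config.marker_ids[1])
    return counts, md, annotation, truth


def toy_counts(values, gene_ids=None, cell_ids=None):
    values = np.asarray(values)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(values.shape[1])]
    return ex.CountMatrix(sp.csr_matrix(values), np.array(gene_ids, dtype=object),
                          np.array(cell_ids, dtype=object))


@pytest.fixture
def toy_counts_factory():
    return toy_counts


@pytest.fixture
def toy_annotation():
    def make(gene_ids, chrom=None, symbols=None, tf=None, ee=None, pc=None):
        n = len(gene_ids)
        return pd.DataFrame({
            "gene_id": gene_ids,
            "symbol": symbols or gene_ids,
            "chromosome_class": chrom or ["autosome"] * n,
            "is_protein_coding": pc if pc is not None else [True] * n,
            "is_tf": tf if tf is not None else [False] * n,
            "is_ee": ee if ee is not None else [False] * n,
        })
    return make
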