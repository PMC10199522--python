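"""Core in-memory containers for the pipeline.

The central object is :class:`CountMatrix`, a genes-by-cells matrix of
non-negative integer counts with unique gene and cell identifiers.  Gene
annotation and per-cell metadata travel as plain :class:`pandas.DataFrame`
objects with declared column names, validated by the helpers below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

CHROMOSOME_CLASSES = ("autosome", "X", "Y")

ANNOTATION_COLUMNS = (
    "gene_id",
    "symbol",
    "chromosome_class",
    "is_protein_coding",
    "is_tf",
    "is_ee",
)

METADATA_COLUMNS = ("cell_id", "stage", "species", "sex")


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer counts.

    Parameters
    ----------
    values
    	Sparse (CSR) or dense integer matrix, genes in rows, cells in columns.
    gene_ids, cell_ids
    	Unique identifier arrays matching the matrix dimensions.
    """

    values: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    _gene_index: dict = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        self.values = self.values.tocsr()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError(
                f"identifier lengths ({len(self.gene_ids)}, {len(self.cell_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene identifiers are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell identifiers are not unique")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        data = self.values.data
        if data.size and not np.allclose(data, np.round(data)):
            raise ValueError("count matrix contains non-integer entries")
        self.values.data = np.asarray(np.round(self.values.data), dtype=np.int64)
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_row(self, gene_id: str) -> np.ndarray:
        """Dense count vector for one gene across all cells."""
        try:
            i = self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"gene identifier not present in matrix: {gene_id!r}")
        return np.asarray(self.values[i].todense()).ravel()

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        idx = self._resolve(mask_or_ids, self.gene_ids)
        return CountMatrix(self.values[idx], self.gene_ids[idx], self.cell_ids)

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        idx = self._resolve(mask_or_ids, self.cell_ids)
        return CountMatrix(self.values[:, idx], self.gene_ids, self.cell_ids[idx])

    @staticmethod
    def _resolve(mask_or_ids, ids: np.ndarray) -> np.ndarray:
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            return np.flatnonzero(arr)
        lookup = {v: i for i, v in enumerate(ids)}
        return np.array([lookup[v] for v in arr], dtype=int)

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def genes_detected_per_cell(self) -> np.ndarray:
        return np.asarray((self.values > 0).sum(axis=0)).ravel()

    def cells_detected_per_gene(self) -> np.ndarray:
        return np.asarray((self.values > 0).sum(axis=1)).ravel()

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.gene_ids, columns=self.cell_ids)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a gene-annotation table (chromosome class + functional flags)."""
    missing = set(ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    if annotation["gene_id"].duplicated().any():
        raise ValueError("annotation gene_ids are not unique")
    bad = set(annotation["chromosome_class"]) - set(CHROMOSOME_CLASSES)
    if bad:
        raise ValueError(f"unknown chromosome classes: {sorted(bad)}")
    return annotation


def validate_metadata(metadata: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    missing = {"cell_id", "stage"} - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata table lacks columns: {sorted(missing)}")
    if metadata["cell_id"].duplicated().any():
        raise ValueError("metadata cell_ids are not unique")
    if counts is not None:
        extra = set(metadata["cell_id"]) ^ set(counts.cell_ids)
        if extra:
            raise ValueError("metadata cell_ids do not match the count matrix")
    return metadata
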