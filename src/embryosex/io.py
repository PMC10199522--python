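"""Reading/writing standard formats plus the QC filters.

Count matrices round-trip through Matrix Market MTX (with ``genes.tsv`` /
``cells.tsv`` sidecars) or dense TSV.  Gene sets use GMT; annotation,
metadata, PPI edge lists and ortholog maps are plain TSV.
"""

from __future__ import annotations

import logging
import os
import warnings

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .containers import CountMatrix, validate_annotation, validate_metadata

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for malformed input files."""


def write_counts(counts: CountMatrix, path: str, format: str = "mtx") -> None:
    """Write counts as MTX (+ genes.tsv / cells.tsv in the same directory) or dense TSV."""
    if format == "mtx":
        sio.mmwrite(path, counts.values.tocoo(), field="integer")
        d = os.path.dirname(os.path.abspath(path))
        pd.Series(counts.gene_ids).to_csv(os.path.join(d, "genes.tsv"),
                                          sep="\t", index=False, header=False)
        pd.Series(counts.cell_ids).to_csv(os.path.join(d, "cells.tsv"),
                                          sep="\t", index=False, header=False)
    elif format == "tsv":
        counts.to_frame().to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format: {format}")


def read_counts(path: str, format: str = "mtx") -> CountMatrix:
    """Read a count matrix; lossless inverse of :func:`write_counts`.

    Raises :class:`FormatError` for negative or non-integer entries, naming
    the offence.
    """
    if format == "mtx":
        try:
            mat = sio.mmread(path)
        except Exception as exc:  # scipy raises assorted types for bad headers
            raise FormatError(f"malformed Matrix Market file {path}: {exc}") from exc
        d = os.path.dirname(os.path.abspath(path))
        genes = pd.read_csv(os.path.join(d, "genes.tsv"), sep="\t", header=None)[0].to_numpy()
        cells = pd.read_csv(os.path.join(d, "cells.tsv"), sep="\t", header=None)[0].to_numpy()
        mat = sp.coo_matrix(mat)
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"dimension mismatch: matrix {mat.shape} vs {len(genes)} genes, "
                f"{len(cells)} cells")
        _check_entries(mat.data, path)
        return CountMatrix(mat.tocsr(), genes, cells)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy()
        _check_entries(values.ravel(), path)
        return CountMatrix(sp.csr_matrix(values), df.index.to_numpy(),
                           df.columns.to_numpy())
    raise ValueError(f"unknown format: {format}")


def _check_entries(data: np.ndarray, path: str) -> None:
    if data.size == 0:
        return
    neg = np.flatnonzero(np.asarray(data) < 0)
    if neg.size:
        raise FormatError(f"{path}: negative entry at data position {neg[0]}")
    arr = np.asarray(data, dtype=float)
    frac = np.flatnonzero(arr != np.round(arr))
    if frac.size:
        raise FormatError(f"{path}: non-integer entry at data position {frac[0]}")


def read_annotation(path: str) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep="\t"))


def write_annotation(annotation: pd.DataFrame, path: str) -> None:
    validate_annotation(annotation).to_csv(path, sep="\t", index=False)


def read_metadata(path: str) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t"))


def write_metadata(metadata: pd.DataFrame, path: str) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_gmt(path: str) -> dict:
    """GMT reader tolerant of a missing description column."""
    sets: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: GMT line needs a name and members")
            name = parts[0]
            # standard GMT is name<TAB>description<TAB>members...; accept a
            # two-column line as name + single member (description omitted)
            raw = parts[2:] if len(parts) >= 3 else parts[1:]
            members = [g for g in raw if g]
            if name in sets:
                raise FormatError(f"{path}:{ln}: duplicate set name {name!r}")
            seen, dedup = set(), []
            for g in members:
                if g not in seen:
                    seen.add(g)
                    dedup.append(g)
            sets[name] = dedup
    return sets


def write_gmt(sets: dict, path: str) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_edge_list(path: str) -> list:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a two-column edge list")
    edges = set()
    for a, b in zip(df[0].astype(str), df[1].astype(str)):
        if a == b:
            continue
        edges.add((a, b) if a <= b else (b, a))
    return sorted(edges)


def write_edge_list(edges, path: str) -> None:
    pd.DataFrame(edges).to_csv(path, sep="\t", index=False, header=False)


def read_ortholog_map(path: str) -> list:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a two-column ortholog map")
    return sorted(set(zip(df[0].astype(str), df[1].astype(str))))


# ---------------------------------------------------------------------------
# QC filters

def filter_counts(counts: CountMatrix, min_cells: int = 3,
                  min_features: int = 350) -> CountMatrix:
    """Remove rarely detected genes, then poorly covered cells.

    Genes detected (count > 0) in fewer than ``min_cells`` cells are removed
    first; cells whose detected-gene count (recomputed after gene removal)
    falls below ``min_features`` are removed second.  The gene-then-cell
    order is fixed, which makes the operation deterministic and idempotent.
    """
    gene_mask = counts.cells_detected_per_gene() >= min_cells
    out = counts.subset_genes(gene_mask)
    cell_mask = out.genes_detected_per_cell() >= min_features
    out = out.subset_cells(cell_mask)
    if out.n_genes == 0 or out.n_cells == 0:
        warnings.warn("QC filtering produced an empty matrix", stacklevel=2)
    return out


def drop_riken(counts: CountMatrix, annotation: pd.DataFrame) -> CountMatrix:
    """Remove genes whose symbol carries the RIKEN clone suffix ("Rik", case-insensitive)."""
    symbols = annotation.set_index("gene_id")["symbol"]
    sym = pd.Series(counts.gene_ids).map(symbols).fillna("")
    is_rik = sym.str.lower().str.endswith("rik").to_numpy()
    n = int(is_rik.sum())
    logger.info("drop_riken: removing %d RIKEN-annotated genes", n)
    if n == counts.n_genes:
        warnings.warn("all genes carried RIKEN suffixes; matrix left empty", stacklevel=2)
    return counts.subset_genes(~is_rik)


def expressed_fraction(counts: CountMatrix, annotation: pd.DataFrame,
                       metadata: pd.DataFrame, group_by: str = "sex") -> pd.DataFrame:
    """Fraction of annotated genes detected per group and chromosome class.

    A gene counts as expressed in a group when it has count > 0 in at least
    one cell of that group.  Groups with zero cells yield missing fractions.
    """
    if group_by not in metadata.columns:
        raise ValueError(f"metadata lacks grouping column {group_by!r}")
    ann = annotation.set_index("gene_id")
    missing = set(counts.gene_ids) - set(ann.index)
    if missing:
        raise ValueError(f"annotation does not cover {len(missing)} matrix genes")
    chrom = ann.loc[counts.gene_ids, "chromosome_class"].to_numpy()
    md = metadata.set_index("cell_id").loc[counts.cell_ids]
    rows = []
    groups = md[group_by].dropna().unique()
    for group in groups:
        cols = np.flatnonzero((md[group_by] == group).to_numpy())
        detected = (np.asarray(counts.values[:, cols].sum(axis=1)).ravel() > 0
                    if cols.size else np.zeros(counts.n_genes, dtype=bool))
        for cls in ("autosome", "X", "Y"):
            in_cls = chrom == cls
            n_ann = int(in_cls.sum())
            frac = float(detected[in_cls].sum() / n_ann) if n_ann and cols.size else np.nan
            rows.append({"group": group, "chromosome_class": cls,
                         "n_annotated": n_ann,
                         "n_expressed": int(detected[in_cls].sum()) if cols.size else 0,
                         "fraction": frac})
    return pd.DataFrame(rows)
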