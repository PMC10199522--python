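"""Sample-level PCA and per-gene variance partitioning into stage and sex.

PCA is run on log-normalized, per-gene-centered, unscaled values.  Variance
partitioning is one-way per gene: the fraction explained by stage is the
R-squared of the stage factor over all cells, and the fraction explained by
sex is the R-squared of the sex factor within each stage's cells — matching
a per-stage readout of how much sex contributes early versus late.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def pca_samples(norm: pd.DataFrame, n_components: int = 15):
    """Principal components of samples (columns of ``norm``).

    Returns
    -------
    scores : DataFrame (samples x components)
    variance_fractions : ndarray, fraction of total variance per component
    gene_loadings : DataFrame (genes x components)
    """
    if norm.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = norm.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)  # center each gene
    n_components = min(n_components, min(Xc.shape) - 0)
    # samples as observations: SVD of the cells x genes matrix
    U, s, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    total = float((s ** 2).sum())
    k = min(n_components, len(s))
    fractions = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * s[:k], index=norm.columns, columns=comp_names)
    loadings = pd.DataFrame(Vt[:k].T, index=norm.index, columns=comp_names)
    return scores, fractions, loadings


def _oneway_r2(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-row R-squared of a categorical factor: SS_between / SS_total."""
    grand = X.mean(axis=1, keepdims=True)
    ss_total = ((X - grand) ** 2).sum(axis=1)
    ss_between = np.zeros(X.shape[0])
    for lev in np.unique(labels):
        cols = labels == lev
        n = int(cols.sum())
        if n == 0:
            continue
        m = X[:, cols].mean(axis=1)
        ss_between += n * (m - grand.ravel()) ** 2
    out = np.zeros(X.shape[0])
    nz = ss_total > 0
    out[nz] = ss_between[nz] / ss_total[nz]
    return np.clip(out, 0.0, 1.0)


def variance_explained(norm: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-gene variance fractions: stage overall, sex within each stage.

    Stages containing a single sex get missing (NaN) sex fractions; genes
    constant over the relevant cells get 0.
    """
    md = metadata.set_index("cell_id").loc[norm.columns]
    if "stage" not in md or "sex" not in md:
        raise ValueError("metadata needs stage and sex columns")
    X = norm.to_numpy(dtype=float)
    stage = md["stage"].to_numpy()
    sex = md["sex"].to_numpy()
    table = pd.DataFrame({"gene_id": norm.index,
                          "frac_stage": _oneway_r2(X, stage)})
    stages = (md["stage"].cat.categories if isinstance(md["stage"].dtype, pd.CategoricalDtype)
              else pd.unique(stage))
    for s in stages:
        cols = stage == s
        col_name = f"frac_sex_{s}"
        if cols.sum() < 2 or len(np.unique(sex[cols])) < 2:
            table[col_name] = np.nan
            continue
        table[col_name] = _oneway_r2(X[:, cols], sex[cols])
    return table
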