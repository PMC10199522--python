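"""Pooled deconvolution size factors and log-normalization.

Sparse single-cell counts defeat per-cell median-of-ratios scaling because
most gene-wise ratios are 0/0.  The deconvolution estimator sidesteps the
zeros by summing counts over overlapping pools of cells: pool-level scaling
factors against an average pseudo-cell are well behaved, and the per-cell
factors are recovered from the pooled linear system by least squares.

Cells are ordered on a ring by library size so each pool mixes small and
large cells; every cell also contributes one low-weight augmentation row
tying its factor to its library-size factor, which anchors the otherwise
scale-free system without ridge regularization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import lsqr

from .containers import CountMatrix

DEFAULT_POOL_SIZES = (21, 41, 61, 81, 101)
_AUGMENT_WEIGHT = 1e-4
_FLOOR = 1e-8


def deconvolution_size_factors(counts: CountMatrix,
                               pool_sizes=DEFAULT_POOL_SIZES,
                               min_mean: float = 0.1) -> np.ndarray:
    """Per-cell size factors by pooled deconvolution, rescaled to mean 1.

    Parameters
    ----------
    counts
        Raw integer counts, genes x cells.
    pool_sizes
        Ring-window widths; each width contributes one pooled equation per
        ring position.  Sizes are clipped to ``n_cells - 1``.
    min_mean
        Genes with average count below this are excluded from the pooled
        median ratios (their ratios are dominated by zeros).
    """
    n_cells = counts.n_cells
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    pool_sizes = sorted({min(int(w), n_cells - 1) for w in pool_sizes if w >= 1})
    if not pool_sizes:
        raise ValueError("no usable pool sizes")

    X = np.asarray(counts.values.todense(), dtype=float)
    gene_means = X.mean(axis=1)
    keep = gene_means >= min_mean
    if not keep.any():
        raise ValueError(f"no genes pass min_mean={min_mean}; cannot deconvolve")
    Xk = X[keep]
    ref = Xk.mean(axis=1)  # average pseudo-cell over retained genes
    ref[ref == 0] = np.nan  # cannot happen when min_mean > 0, defensive

    lib = counts.library_sizes().astype(float)
    if (lib == 0).any():
        raise ValueError("cells with zero library size; filter before normalizing")
    order = np.argsort(lib, kind="stable")
    ring = np.concatenate([order, order])  # wrap-around windows

    rows, cols, vals, b = [], [], [], []
    r = 0
    for w in pool_sizes:
        # cumulative sums over the ring give pooled counts per window
        for start in range(n_cells):
            pool = ring[start:start + w]
            pooled = Xk[:, pool].sum(axis=1)
            theta = float(np.nanmedian(pooled / ref))
            rows.extend([r] * w)
            cols.extend(pool.tolist())
            vals.extend([1.0] * w)
            b.append(theta)
            r += 1
    # augmentation: softly tie each cell to its library-size factor
    ls_factor = lib / lib.mean()
    for j in range(n_cells):
        rows.append(r)
        cols.append(j)
        vals.append(_AUGMENT_WEIGHT)
        b.append(_AUGMENT_WEIGHT * ls_factor[j])
        r += 1

    A = sp.csr_matrix((vals, (rows, cols)), shape=(r, n_cells))
    sol = lsqr(A, np.asarray(b), atol=1e-12, btol=1e-12, iter_lim=20 * n_cells)
    t, istop = sol[0], sol[1]
    if istop not in (1, 2):
        raise RuntimeError(f"deconvolution system could not be solved (lsqr istop={istop})")
    if (t <= 0).any():
        warnings.warn(f"{int((t <= 0).sum())} non-positive size factors floored",
                      stacklevel=2)
        t = np.maximum(t, _FLOOR)
    return t / t.mean()


def library_size_factors(counts: CountMatrix) -> np.ndarray:
    """Plain library-size factors (mean 1); the deconvolution baseline."""
    lib = counts.library_sizes().astype(float)
    return lib / lib.mean()


def log_normalize(counts: CountMatrix, sf: np.ndarray,
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), genes x cells."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    sf = np.asarray(sf, dtype=float)
    if sf.shape != (counts.n_cells,) or (sf <= 0).any():
        raise ValueError("size factors must be positive, one per cell")
    X = np.asarray(counts.values.todense(), dtype=float)
    out = np.log2(X / sf[None, :] + pseudocount)
    return pd.DataFrame(out, index=counts.gene_ids, columns=counts.cell_ids)
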