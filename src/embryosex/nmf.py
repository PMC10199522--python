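"""Non-negative matrix factorization with consensus rank selection.

``V ~ W H`` is fit by multiplicative updates minimizing the generalized
Kullback-Leibler divergence D(V || WH) (the classical Lee-Seung algorithm,
whose objective is non-increasing per update).  For rank selection, the
factorization is repeated from ``n_runs`` seeded random starts; samples are
co-clustered by the argmax row of H, the run-averaged co-assignment matrix
is the consensus, and the cophenetic correlation between consensus
dissimilarities and their average-linkage dendrogram measures partition
stability.  The chosen rank maximizes the cophenetic coefficient (smallest
rank on ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class NMFModel:
    V: np.ndarray
    W: np.ndarray  # genes x k loadings
    H: np.ndarray  # k x samples mixtures
    objective_trace: list
    seed: int
    converged: bool = False


@dataclass
class RankSelection:
    ranks: list
    cophenetic: list
    chosen_rank: int
    consensus: dict = field(default_factory=dict, repr=False)


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH) with the 0 log 0 = 0 convention."""
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    term = np.zeros_like(V, dtype=float)
    term[mask] = V[mask] * np.log(V[mask] / WH[mask])
    return float(term.sum() - V.sum() + WH.sum())


def _init(V: np.ndarray, k: int, rng: np.random.Generator):
    # uniform (0, 1] entries scaled so WH matches the data mean
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = (1.0 - rng.random((V.shape[0], k))) * scale
    H = (1.0 - rng.random((k, V.shape[1]))) * scale
    return W, H


def nmf_fit(V: np.ndarray, k: int, seed: int = 0, max_iter: int = 500,
            tol: float = 1e-6) -> NMFModel:
    """Multiplicative-update KL NMF from a seeded uniform start."""
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("V must be non-negative")
    if k < 1:
        raise ValueError("rank must be >= 1")
    rng = np.random.default_rng(seed)
    W, H = _init(V, k, rng)
    trace = []
    prev = None
    converged = False
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1)[None, :], _EPS)
        WH = np.maximum(W @ H, _EPS)
        H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        obj = kl_divergence(V, W @ H)
        trace.append(obj)
        if prev is not None and prev - obj <= tol * max(abs(prev), 1.0):
            converged = True
            break
        prev = obj
    return NMFModel(V=V, W=W, H=H, objective_trace=trace, seed=seed,
                    converged=converged)


def sample_partition(model: NMFModel) -> np.ndarray:
    """Cluster label per sample: argmax over the rows of H."""
    return model.H.argmax(axis=0)


def consensus_matrix(partitions) -> np.ndarray:
    """Fraction of runs in which each sample pair is co-assigned."""
    parts = np.asarray(list(partitions))
    if parts.ndim != 2 or parts.shape[0] < 2:
        raise ValueError("need at least 2 run partitions")
    co = (parts[:, :, None] == parts[:, None, :]).mean(axis=0)
    return co


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Correlation between consensus dissimilarities and their dendrogram.

    Average-linkage hierarchical clustering of ``1 - consensus``; returns 1
    exactly when the consensus is a perfect block partition.
    """
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    if np.allclose(condensed, condensed[0] if condensed.size else 0.0):
        return 1.0  # all pairwise dissimilarities equal: dendrogram is exact
    Z = average(condensed)
    c, _ = cophenet(Z, condensed)
    return float(c)


def consensus_and_cophenetic(V: np.ndarray, k: int, n_runs: int = 10,
                             seeds=None, max_iter: int = 500,
                             tol: float = 1e-6):
    """Consensus matrix over repeated runs plus its cophenetic coefficient."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if seeds is None:
        seeds = range(n_runs)
    seeds = list(seeds)[:n_runs]
    parts = [sample_partition(nmf_fit(V, k, seed=s, max_iter=max_iter, tol=tol))
             for s in seeds]
    C = consensus_matrix(parts)
    return C, cophenetic_coefficient(C)


def select_rank(V: np.ndarray, ranks=range(5, 31), n_runs: int = 10,
                seeds=None, max_iter: int = 500, tol: float = 1e-6) -> RankSelection:
    """Cophenetic-curve rank selection; ties go to the smallest rank."""
    V = np.asarray(V, dtype=float)
    ranks = list(ranks)
    max_rank = min(V.shape) - 1
    if any(k < 1 or k > max_rank for k in ranks):
        raise ValueError(f"ranks must lie in [1, {max_rank}] for this matrix")
    coph, consensus = [], {}
    for k in ranks:
        base = 1000 * k
        run_seeds = seeds if seeds is not None else range(base, base + n_runs)
        C, c = consensus_and_cophenetic(V, k, n_runs=n_runs, seeds=run_seeds,
                                        max_iter=max_iter, tol=tol)
        consensus[k] = C
        coph.append(c)
        logger.info("rank %d: cophenetic %.4f", k, c)
    best = int(np.argmax(coph))  # argmax returns the first (smallest) on ties
    return RankSelection(ranks=ranks, cophenetic=coph,
                         chosen_rank=ranks[best], consensus=consensus)


def metagene_membership(model: NMFModel, gene_ids=None,
                        norm: pd.DataFrame | None = None,
                        metadata: pd.DataFrame | None = None):
    """Assign genes to metagenes by the argmax of their W row.

    All-zero rows are left unassigned (label -1) with a logged count.  When
    ``norm`` and ``metadata`` are given, per-metagene mean expression
    profiles by stage (and by sex, if present) are returned alongside.
    """
    W = model.W
    labels = W.argmax(axis=1)
    zero = ~(W > 0).any(axis=1)
    if zero.any():
        logger.info("metagene_membership: %d all-zero gene rows unassigned",
                    int(zero.sum()))
    labels = np.where(zero, -1, labels)
    if gene_ids is None:
        gene_ids = np.arange(W.shape[0])
    membership = dict(zip(gene_ids, labels.tolist()))
    if norm is None or metadata is None:
        return membership, None
    md = metadata.set_index("cell_id").loc[norm.columns]
    group_cols = ["stage", "sex"] if "sex" in md.columns else ["stage"]
    rows = []
    for m in sorted(set(labels) - {-1}):
        genes = [g for g, lab in membership.items() if lab == m and g in norm.index]
        sub = norm.loc[genes]
        grouped = sub.T.groupby([md[c] for c in group_cols], observed=True).mean()
        prof = grouped.mean(axis=1)
        for key, val in prof.items():
            key = key if isinstance(key, tuple) else (key,)
            rows.append({"metagene": m, **dict(zip(group_cols, key)),
                         "mean_expression": float(val)})
    return membership, pd.DataFrame(rows)
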