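"""Pre-ranked gene set enrichment with a gene-permutation null.

Genes are ranked by a non-negative score (here: a metagene's loadings).  The
enrichment score (ES) is the maximum of the classical weighted
Kolmogorov-Smirnov running sum: walking down the ranking, hitting a set
member adds ``|w|^p`` normalized by the set's total weight, and missing
subtracts ``1/(N - |set|)``.  Positive-mode scoring takes the running
maximum.  Significance comes from a Monte-Carlo null that redraws the set's
gene labels uniformly (preserving set size); ``NES = ES / mean(null ES)``
and BH correction is applied across sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def enrichment_score(ranked, gene_set, exponent: float = 1.0):
    """(ES, running profile) of ``gene_set`` against an ordered ranking.

    ``ranked`` is a sequence of (gene, weight) pairs ordered best-first with
    non-negative weights.
    """
    genes = [g for g, _ in ranked]
    weights = np.array([w for _, w in ranked], dtype=float)
    if (weights < 0).any():
        raise ValueError("weights must be non-negative under positive scoring")
    members = set(gene_set) & set(genes)
    if not members:
        raise ValueError("gene set does not intersect the ranked list")
    N = len(genes)
    hit = np.array([g in members for g in genes])
    if hit.all():
        raise ValueError("gene set covers the whole ranked list")
    wp = np.abs(weights) ** exponent
    hit_mass = wp * hit
    total_hit = hit_mass.sum()
    if total_hit == 0:
        # all member weights zero: fall back to equal hit increments
        hit_mass = hit.astype(float)
        total_hit = hit_mass.sum()
    steps = hit_mass / total_hit - (~hit) / (N - len(members))
    running = np.cumsum(steps)
    es = float(running.max())
    return es, running


def _es_only(order_weights: np.ndarray, hit: np.ndarray, n_members: int) -> float:
    total = order_weights[hit].sum()
    if total == 0:
        steps = hit / hit.sum() - (~hit) / (len(hit) - n_members)
    else:
        steps = np.where(hit, order_weights / total, -1.0 / (len(hit) - n_members))
    return float(np.cumsum(steps).max())


def gsea_preranked(scores: pd.Series, collection: dict, min_size: int = 15,
                   max_size: int = 500, n_perm: int = 1000, seed: int = 0,
                   exponent: float = 1.0) -> pd.DataFrame:
    """Pre-ranked GSEA of every set in ``collection`` against ``scores``.

    ``scores`` maps gene -> non-negative weight (e.g. a W column); ties are
    broken by gene identifier order.  Permutation p-values use the +1
    convention ``(1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = scores.astype(float)
    if (scores < 0).any():
        raise ValueError("scores must be non-negative")
    # rank: descending weight, gene id as tie-break
    ordered = scores.loc[sorted(scores.index)].sort_values(
        ascending=False, kind="stable")
    genes = np.asarray(ordered.index, dtype=object)
    weights = ordered.to_numpy() ** exponent
    universe = set(genes)
    N = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in collection.items():
        inside = sorted(set(members) & universe)
        size = len(inside)
        if size < min_size or size > max_size or size == N:
            continue
        hit = np.zeros(N, dtype=bool)
        hit[[pos[g] for g in inside]] = True
        es = _es_only(weights, hit, size)
        running_top = np.argmax(np.cumsum(
            np.where(hit, weights / max(weights[hit].sum(), 1e-300),
                     -1.0 / (N - size))))
        leading = [g for g in genes[:running_top + 1] if g in set(inside)]
        null = np.empty(n_perm)
        for b in range(n_perm):
            idx = rng.choice(N, size=size, replace=False)
            h = np.zeros(N, dtype=bool)
            h[idx] = True
            null[b] = _es_only(weights, h, size)
        p = (1.0 + float((null >= es).sum())) / (1.0 + n_perm)
        nes = es / null.mean() if null.mean() > 0 else np.nan
        rows.append({"set": name, "ES": es, "NES": nes, "pvalue": p,
                     "size": size, "leading_edge": leading})
    if not rows:
        warnings.warn("no gene sets survived size filtering", stacklevel=2)
        return pd.DataFrame(columns=["set", "ES", "NES", "pvalue", "padj",
                                     "size", "leading_edge"])
    out = pd.DataFrame(rows)
    out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out[["set", "ES", "NES", "pvalue", "padj", "size", "leading_edge"]]


def enrichment_heatmap_table(results: dict, alpha: float = 0.05):
    """Concordance of significant pathways across (species, sex, metagene).

    ``results`` maps a (species, sex, metagene) key to a GSEA result table.
    Returns (long-format indicator table, per-pathway normalized counts of
    enriched clusters, where each cluster's contribution is divided by the
    number of sets it enriched).
    """
    if not results:
        raise ValueError("no result tables supplied")
    rows = []
    for key, table in results.items():
        if not isinstance(key, tuple):
            key = (key,)
        sig = table[table["padj"] < alpha]
        for _, r in sig.iterrows():
            rows.append({"pathway": r["set"],
                         "key": key,
                         "NES": r["NES"],
                         "padj": r["padj"]})
    indicator = pd.DataFrame(rows, columns=["pathway", "key", "NES", "padj"])
    # normalized count: per pathway, sum over clusters of 1 / cluster_size
    cluster_sizes = {(k if isinstance(k, tuple) else (k,)):
                     max(int((t["padj"] < alpha).sum()), 1)
                     for k, t in results.items()}
    norm_rows = []
    for pathway, grp in indicator.groupby("pathway"):
        val = sum(1.0 / cluster_sizes[k] for k in grp["key"])
        norm_rows.append({"pathway": pathway, "n_clusters": len(grp),
                          "normalized_count": val})
    normalized = pd.DataFrame(norm_rows,
                              columns=["pathway", "n_clusters", "normalized_count"])
    return indicator, normalized
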