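"""Cross-species conservation of stage expression profiles for orthologs.

Cells of each species are binned into shared "generalized developmental
groups" (S1..S4) so sparse early stages of one species can be compared with
the other's.  For each ortholog pair, the group-mean expression profile is
z-scored within its species and the conservation score is the Pearson
correlation of the two profiles across groups.  Significance comes from a
pairing-permutation null: the ortholog assignment is shuffled ``n_perm``
times and p is the +1-corrected fraction of shuffles whose score reaches
the observed one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def assign_generalized_stages(metadata: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """Attach a ``group`` column from a stage -> group mapping.

    Every stage present in the metadata must be mapped; unmapped stages
    raise, naming the offender.
    """
    md = metadata.copy()
    stages = pd.unique(md["stage"].dropna())
    missing = [s for s in stages if s not in mapping]
    if missing:
        raise ValueError(f"stages missing from the group mapping: {missing}")
    md["group"] = md["stage"].astype(object).map(mapping)
    return md


def _group_profiles(norm: pd.DataFrame, grouped_md: pd.DataFrame, groups) -> pd.DataFrame:
    md = grouped_md.set_index("cell_id")
    cols = [c for c in norm.columns if c in md.index]
    profs = {}
    for g in groups:
        cells = [c for c in cols if md.loc[c, "group"] == g]
        if not cells:
            raise ValueError(f"group {g} has no cells")
        profs[g] = norm[cells].mean(axis=1)
    return pd.DataFrame(profs)


def _zscore_rows(P: np.ndarray) -> np.ndarray:
    m = P.mean(axis=1, keepdims=True)
    s = P.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (P - m) / s
    return Z  # constant rows become NaN and score as missing


def conservation_scores(normA: pd.DataFrame, normB: pd.DataFrame,
                        groupedA: pd.DataFrame, groupedB: pd.DataFrame,
                        orthologs, n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Per-ortholog-pair profile correlation with a pairing-permutation p.

    ``orthologs`` is a list of (gene_A, gene_B) pairs; pairs with either
    gene missing from its expression table are excluded.  The result is
    ranked by p-value then descending score.
    """
    groups = sorted(set(groupedA["group"].dropna()) & set(groupedB["group"].dropna()))
    if len(groups) < 2:
        raise ValueError("need at least 2 shared groups with cells in both species")
    profA = _group_profiles(normA, groupedA, groups)
    profB = _group_profiles(normB, groupedB, groups)
    pairs = [(a, b) for a, b in dict.fromkeys(orthologs)
             if a in profA.index and b in profB.index]
    if not pairs:
        raise ValueError("no ortholog pairs map into both expression tables")
    A = _zscore_rows(profA.loc[[a for a, _ in pairs]].to_numpy(dtype=float))
    B = _zscore_rows(profB.loc[[b for _, b in pairs]].to_numpy(dtype=float))
    k = len(groups)
    score = (A * B).sum(axis=1) / k  # Pearson r of the z-scored profiles

    rng = np.random.default_rng(seed)
    n = len(pairs)
    exceed = np.zeros(n)
    valid_perm = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        perm_score = (A * B[perm]).sum(axis=1) / k
        exceed += (perm_score >= score) | np.isnan(score)
        valid_perm += 1
    pvals = (1.0 + exceed) / (1.0 + valid_perm)
    out = pd.DataFrame({
        "gene_a": [a for a, _ in pairs],
        "gene_b": [b for _, b in pairs],
        "score": score,
        "pvalue": np.where(np.isnan(score), np.nan, pvals),
    })
    for gi, g in enumerate(groups):
        out[f"profile_a_{g}"] = profA.loc[[a for a, _ in pairs], g].to_numpy()
        out[f"profile_b_{g}"] = profB.loc[[b for _, b in pairs], g].to_numpy()
    out = out.sort_values(["pvalue", "score"], ascending=[True, False],
                          kind="stable", na_position="last")
    return out.reset_index(drop=True)


def top_expression_mask(norm: pd.DataFrame, q: float = 0.9) -> pd.DataFrame:
    """Boolean mask: entries strictly above the gene's q-quantile across samples."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    thresh = norm.quantile(q, axis=1)
    return norm.gt(thresh, axis=0)
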