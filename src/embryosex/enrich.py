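"""Over/under-enrichment of sexDEGs by functional class and chromosome.

Each (stage, bias direction, category) cell is a hypergeometric draw: the
universe is the genes expressed at that stage, the category is a functional
class (protein-coding, TF, epigenetic-enzyme) or chromosome class, and the
"successes" are the stage's sexDEGs of one direction.  ``p_over`` and
``p_under`` are one-tailed probabilities including the observed point; cells
with fewer than 5 DEGs or category members are flagged low-confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

LOW_CONFIDENCE_MIN = 5

CATEGORY_DEFS = {
    "protein_coding": lambda ann: ann["is_protein_coding"],
    "tf": lambda ann: ann["is_tf"],
    "ee": lambda ann: ann["is_ee"],
    "autosome": lambda ann: ann["chromosome_class"] == "autosome",
    "X": lambda ann: ann["chromosome_class"] == "X",
    "Y": lambda ann: ann["chromosome_class"] == "Y",
}


@dataclass
class EnrichmentCell:
    stage: str
    direction: str
    category: str
    n_universe: int
    n_category: int
    n_deg: int
    n_overlap: int
    fold: float
    p_over: float
    p_under: float
    low_confidence: bool


def hypergeom_enrichment(universe, category_set, deg_set,
                         stage: str = "", direction: str = "",
                         category: str = "") -> EnrichmentCell:
    """One-tailed hypergeometric over- and under-enrichment probabilities."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    category_set = set(category_set) & universe
    deg_set = set(deg_set) & universe
    if set(category_set) - universe or set(deg_set) - universe:
        raise ValueError("category and DEG sets must lie within the universe")
    N, K, n = len(universe), len(category_set), len(deg_set)
    k = len(category_set & deg_set)
    rv = hypergeom(N, K, n)
    p_over = float(rv.sf(k - 1))   # P(X >= k)
    p_under = float(rv.cdf(k))     # P(X <= k)
    fold = np.nan
    if n > 0 and K > 0:
        fold = (k / n) / (K / N)
    return EnrichmentCell(
        stage=stage, direction=direction, category=category,
        n_universe=N, n_category=K, n_deg=n, n_overlap=k, fold=fold,
        p_over=p_over, p_under=p_under,
        low_confidence=(n < LOW_CONFIDENCE_MIN or K < LOW_CONFIDENCE_MIN),
    )


def enrichment_grid(classified_results: dict, annotation: pd.DataFrame) -> pd.DataFrame:
    """Stage x direction x category enrichment table.

    ``classified_results`` maps stage -> DE table with ``gene_id`` and
    ``bias`` columns; the universe per stage is the genes tested there
    (i.e. expressed at the stage).
    """
    ann = annotation.set_index("gene_id")
    rows = []
    for stage, res in classified_results.items():
        universe = list(res["gene_id"])
        ann_stage = ann.reindex(universe)
        for direction in ("female", "male"):
            degs = set(res.loc[res["bias"] == direction, "gene_id"])
            for cat, selector in CATEGORY_DEFS.items():
                members = set(ann_stage.index[selector(ann_stage).fillna(False)])
                cell = hypergeom_enrichment(universe, members, degs,
                                            stage=stage, direction=direction,
                                            category=cat)
                rows.append(cell.__dict__)
    return pd.DataFrame(rows)


def regulator_census(norm: pd.DataFrame, annotation: pd.DataFrame,
                     metadata: pd.DataFrame, top_n: int = 1000) -> pd.DataFrame:
    """TF and epigenetic-enzyme counts among each stage's top-expressed genes.

    Genes are ranked per stage by mean normalized expression; ties break by
    gene identifier order.
    """
    ann = annotation.set_index("gene_id")
    md = metadata.set_index("cell_id")
    md = md.loc[[c for c in norm.columns if c in md.index]]
    rows = []
    for stage in pd.unique(md["stage"].dropna()):
        cols = md.index[md["stage"] == stage]
        means = norm[cols].mean(axis=1)
        # stable sort on descending mean after sorting the index gives the
        # declared gene-id tie-break
        ranked = means.loc[sorted(means.index)].sort_values(
            ascending=False, kind="stable")
        n = min(top_n, len(ranked))
        if n < top_n:
            warnings.warn(f"stage {stage}: only {n} genes available for top_{top_n}",
                          stacklevel=2)
        top = ranked.index[:n]
        sub = ann.reindex(top)
        rows.append({"stage": stage, "top_n": n,
                     "n_tf": int(sub["is_tf"].fillna(False).sum()),
                     "n_ee": int(sub["is_ee"].fillna(False).sum())})
    return pd.DataFrame(rows)
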