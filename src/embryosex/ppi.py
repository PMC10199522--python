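"""Stage-wise protein-protein interaction networks over expressed genes.

At each stage the PPI edge list is restricted to genes expressed there, each
node is labelled male-biased (M), female-biased (F) or non-DE (N), and the
edges are tallied into the six unordered endpoint classes {MM, FF, NN, MN,
FN, MF}.  Within-class counts are normalized by that class's gene count;
cross-class counts by the geometric mean of the two class sizes.  A hive
layout export places nodes on class axes ordered by degree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EDGE_CLASSES = ("MM", "FF", "NN", "MN", "FN", "MF")


def stage_subgraph(edges, expressed_genes) -> list:
    """Edges whose endpoints are both expressed at the stage."""
    expressed = set(expressed_genes)
    return sorted({tuple(sorted(e)) for e in edges
                   if e[0] in expressed and e[1] in expressed and e[0] != e[1]})


def classify_edges(subgraph, male_degs, female_degs, stage: str = "") -> pd.DataFrame:
    """Counts and normalized counts of the six DE edge classes.

    Returns a one-row table: raw count, class sizes and normalized count per
    class; classes with an empty size denominator report missing, not zero.
    """
    male_degs, female_degs = set(male_degs), set(female_degs)
    if male_degs & female_degs:
        raise ValueError("male and female DEG sets overlap")

    def label(g):
        if g in male_degs:
            return "M"
        if g in female_degs:
            return "F"
        return "N"

    counts = dict.fromkeys(EDGE_CLASSES, 0)
    nodes = set()
    for a, b in subgraph:
        nodes.update((a, b))
        pair = "".join(sorted((label(a), label(b))))
        key = {"MM": "MM", "FF": "FF", "NN": "NN",
               "MN": "MN", "FN": "FN", "FM": "MF"}[pair]
        counts[key] += 1
    sizes = {"M": len([g for g in nodes if label(g) == "M"]),
             "F": len([g for g in nodes if label(g) == "F"]),
             "N": len([g for g in nodes if label(g) == "N"])}

    def denom(cls):
        a, b = cls[0], cls[1]
        if a == b:
            return sizes[a] if sizes[a] > 0 else np.nan
        gm = np.sqrt(sizes[a] * sizes[b])
        return gm if gm > 0 else np.nan

    row = {"stage": stage, "n_edges": len(subgraph),
           "size_M": sizes["M"], "size_F": sizes["F"], "size_N": sizes["N"]}
    for cls in EDGE_CLASSES:
        row[f"count_{cls}"] = counts[cls]
        d = denom(cls)
        row[f"norm_{cls}"] = counts[cls] / d if np.isfinite(d) else np.nan
    return pd.DataFrame([row])


def hive_layout_export(subgraph, male_degs, female_degs) -> pd.DataFrame:
    """Axis/position table for a hive plot of the classified network.

    Each class gets a pair of axes (M: 1a/1b, F: 2a/2b, N: 3a/3b); nodes
    alternate between the pair in degree order, position = rank within the
    axis.  Ties in degree break by gene identifier.
    """
    male_degs, female_degs = set(male_degs), set(female_degs)
    degree: dict = {}
    for a, b in subgraph:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    axis_base = {"M": "1", "F": "2", "N": "3"}
    rows = []
    by_class: dict = {"M": [], "F": [], "N": []}
    for g in degree:
        cls = "M" if g in male_degs else "F" if g in female_degs else "N"
        by_class[cls].append(g)
    for cls, members in by_class.items():
        members.sort(key=lambda g: (-degree[g], g))
        pos = {"a": 0, "b": 0}
        for i, g in enumerate(members):
            sub = "a" if i % 2 == 0 else "b"
            rows.append({"gene_id": g, "class": cls,
                         "axis": axis_base[cls] + sub,
                         "position": pos[sub], "degree": degree[g]})
            pos[sub] += 1
    return pd.DataFrame(rows, columns=["gene_id", "class", "axis",
                                       "position", "degree"])
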