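"""Marker-based sex assignment for single cells.

Cells are sexed from the raw counts of two early-expressed markers: an
X-linked female marker (Xist in mouse) and a Y-linked male marker (Eif2s3y).
The X marker doubles as a signal-sufficiency control: cells expressing
neither marker are ambiguous.  The rule, applied per cell:

* Y marker absent, X marker present  -> female
* Y marker present, X/Y ratio < 1    -> male
* X/Y ratio >= 1, or both markers 0  -> ambiguous (removed downstream)

Datasets whose cells were sexed upstream by Y-linked expression can instead
use ``mode="y_presence"``: male iff summed Y-linked counts exceed a
threshold (default 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SexCall:
    label: str  # "male" | "female" | "ambiguous"
    ratio: float  # X/Y marker ratio; NaN when undefined


def call_sex(xist: float, eif2s3y: float) -> SexCall:
    """Sex call from the two marker counts of a single cell."""
    if xist < 0 or eif2s3y < 0:
        raise ValueError("marker counts must be non-negative")
    if eif2s3y == 0:
        if xist > 0:
            return SexCall("female", np.nan)
        return SexCall("ambiguous", np.nan)  # no signal from either marker
    ratio = xist / eif2s3y
    if ratio < 1.0:
        return SexCall("male", ratio)
    return SexCall("ambiguous", ratio)  # ratio >= 1 with Y expression


def sex_dataset(counts: CountMatrix, metadata: pd.DataFrame,
                marker_x_id: str = "Xist", marker_y_id: str = "Eif2s3y",
                mode: str = "ratio", y_threshold: float = 0.0,
                annotation: pd.DataFrame | None = None,
                drop_ambiguous: bool = True) -> pd.DataFrame:
    """Assign sex to every cell and (optionally) drop ambiguous cells.

    Returns a copy of ``metadata`` with ``sex`` and ``sex_ratio`` columns;
    in ratio mode ambiguous cells are removed with a logged count.
    """
    md = metadata.copy()
    if mode == "ratio":
        x = counts.gene_row(marker_x_id).astype(float)
        y = counts.gene_row(marker_y_id).astype(float)
        cell_order = pd.Series(range(counts.n_cells), index=counts.cell_ids)
        idx = cell_order.loc[md["cell_id"]].to_numpy()
        calls = [call_sex(x[i], y[i]) for i in idx]
        md["sex"] = [c.label for c in calls]
        md["sex_ratio"] = [c.ratio for c in calls]
    elif mode == "y_presence":
        if annotation is None:
            raise ValueError("y_presence mode requires a gene annotation table")
        y_genes = annotation.loc[annotation["chromosome_class"] == "Y", "gene_id"]
        present = [g for g in y_genes if g in set(counts.gene_ids)]
        if not present:
            raise ValueError("no annotated Y-linked genes found in the matrix")
        sub = counts.subset_genes(np.asarray(present))
        y_sum = np.asarray(sub.values.sum(axis=0)).ravel()
        per_cell = pd.Series(y_sum, index=counts.cell_ids)
        md["sex"] = np.where(per_cell.loc[md["cell_id"]] > y_threshold,
                             "male", "female")
        md["sex_ratio"] = np.nan
    else:
        raise ValueError(f"unknown sexing mode: {mode}")

    if drop_ambiguous:
        n_amb = int((md["sex"] == "ambiguous").sum())
        if n_amb:
            logger.info("sex_dataset: removing %d ambiguous cells", n_amb)
        md = md[md["sex"] != "ambiguous"].reset_index(drop=True)
    return md
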