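"""Between-type similarity matrices restricted to cell-adhesion molecule genes.

The similarity score between two cell types is the average Pearson
correlation over all cross-type cell pairs, computed on log2(TPM+1) of the
CAM genes only; the diagonal averages within-type pairs excluding self
pairs (a self correlation is always 1 and would bias the diagonal upward).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import Dataset, GeneSet, ValidationError

logger = logging.getLogger(__name__)

GROUPINGS = ("five_types", "axo", "dendro")
_PV_TYPES = ("vAAC", "vBIC", "hBIC", "vBC", "hBC")


def _group_labels(ds: Dataset, group_by: str) -> pd.Series:
    meta = ds.meta.df
    pv = meta["morph_type"].isin(_PV_TYPES)
    if group_by == "five_types":
        return meta.loc[pv, "morph_type"]
    if group_by == "axo":
        return meta.loc[pv, "axo"]
    if group_by == "dendro":
        return meta.loc[pv, "dendro"]
    raise ValidationError(f"unknown grouping {group_by!r}; allowed: {GROUPINGS}")


def cam_similarity(
    ds: Dataset,
    cam_genes: GeneSet,
    group_by: str = "five_types",
    scale: str = "log2",
) -> pd.DataFrame:
    """Mean pairwise cell-cell Pearson correlation between (and within) types.

    ``cam_genes`` should already have passed the expression filter
    (expressed in at least three PV cells).  Cells with constant expression
    over the CAM genes are excluded with a warning.  ``scale`` is ``log2``
    (log2(TPM+1), default) or ``linear``.
    """
    if len(cam_genes) == 0:
        raise ValidationError("empty CAM gene set")
    genes = [g for g in cam_genes if g in set(ds.expr.genes)]
    if len(genes) < 2:
        raise ValidationError("need at least 2 CAM genes present in the matrix")
    labels = _group_labels(ds, group_by)
    if labels.empty:
        raise ValidationError("no PV cells in the dataset")
    values = ds.expr.df.loc[genes, labels.index]
    if scale == "log2":
        values = np.log2(values + 1.0)
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")

    X = values.to_numpy().T  # cells x genes
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        dropped = labels.index[constant].tolist()
        logger.warning("cam_similarity: dropping %d constant cells: %s",
                       len(dropped), dropped[:5])
        X, labels = X[~constant], labels[~constant]
    types = sorted(labels.unique())
    for t in types:
        if (labels == t).sum() < 1:
            raise ValidationError(f"group {t} is empty")
    corr = np.corrcoef(X)
    out = pd.DataFrame(index=types, columns=types, dtype=float)
    for i, ta in enumerate(types):
        ia = np.flatnonzero((labels == ta).to_numpy())
        for tb in types[i:]:
            ib = np.flatnonzero((labels == tb).to_numpy())
            block = corr[np.ix_(ia, ib)]
            if ta == tb:
                n = len(ia)
                if n < 2:
                    val = np.nan  # a single cell has no within-type pair
                else:
                    val = (block.sum() - n) / (n * (n - 1))  # exclude self pairs
            else:
                val = block.mean()
            out.loc[ta, tb] = val
            out.loc[tb, ta] = val
    return out
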