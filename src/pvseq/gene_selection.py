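"""Six gene-selection methods behind one interface.

Supervised scores (chi-squared on log2(TPM+1); mutual information and ANOVA
F on the binary expressed indicator), a fixed reference list, genes
correlated with a reference list, and a rate-adjusted variable-gene rule
with a TPM > 32 cutoff.  All methods are deterministic and permutation
equivariant in the cells; ties are broken alphabetically by gene symbol.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import chi2, f_classif, mutual_info_classif

from .data import Dataset, GeneSet, ValidationError
from .qc_de import EXPRESSED_CUTOFF_TPM

logger = logging.getLogger(__name__)

SUPERVISED_METHODS = ("chi2", "mutual_info", "anova_f")
REFERENCE_METHODS = ("reference_list", "correlated_with_reference")
ALL_METHODS = SUPERVISED_METHODS + REFERENCE_METHODS + ("rate_adjusted_variable",)


@dataclass
class SelectionRequest:
    method: str
    n_genes: int = 150
    labels: list | None = None
    reference_genes: GeneSet | None = None
    tpm_cutoff: float = 32.0
    expressed_cutoff_tpm: float = EXPRESSED_CUTOFF_TPM

    def __post_init__(self):
        if self.method not in ALL_METHODS:
            raise ValidationError(f"unknown method {self.method!r}; allowed: {ALL_METHODS}")
        if self.method in SUPERVISED_METHODS and self.labels is None:
            raise ValidationError(f"method {self.method!r} requires per-cell labels")
        if self.method in REFERENCE_METHODS and self.reference_genes is None:
            raise ValidationError(f"method {self.method!r} requires reference_genes")


def _rank_by_score(genes: pd.Index, scores: np.ndarray, n: int) -> GeneSet:
    """Descending score, ties broken alphabetically; NaN scores sink to 0."""
    scores = np.where(np.isnan(scores), 0.0, scores)
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    take = order[: min(n, len(order))]
    return GeneSet(method="", genes=[genes[i] for i in take],
                   scores=[float(scores[i]) for i in take])


def select_genes(ds: Dataset, req: SelectionRequest) -> GeneSet:
    """Dispatch one of the six selection methods; returns a ranked GeneSet."""
    genes = ds.expr.genes
    n = req.n_genes
    if n > len(genes):
        warnings.warn(f"requested {n} genes but only {len(genes)} available")
        n = len(genes)

    if req.method in SUPERVISED_METHODS:
        y = np.asarray(req.labels)
        if len(y) != ds.n_cells:
            raise ValidationError("labels length must equal number of cells")
        if req.method == "chi2":
            X = ds.expr.log2p1().to_numpy().T  # cells x genes, non-negative
            scores, _ = chi2(X, y)
        else:
            X = (ds.expr.df > req.expressed_cutoff_tpm).to_numpy().T.astype(int)
            if req.method == "mutual_info":
                scores = mutual_info_classif(X, y, discrete_features=True)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    scores, _ = f_classif(X, y)
        gs = _rank_by_score(genes, np.asarray(scores, dtype=float), n)
        gs.method = req.method
        return gs

    if req.method == "reference_list":
        have = set(genes)
        kept = [g for g in req.reference_genes if g in have]
        return GeneSet(method="reference_list", genes=kept[:n] if n < len(kept) else kept)

    if req.method == "correlated_with_reference":
        have = set(genes)
        refs = [g for g in req.reference_genes if g in have]
        if not refs:
            raise ValidationError("no reference gene present in the matrix")
        log = ds.expr.log2p1()
        X = log.to_numpy()
        Xc = X - X.mean(axis=1, keepdims=True)
        sd = Xc.std(axis=1)
        ref_idx = [genes.get_loc(g) for g in refs]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (Xc @ Xc[ref_idx].T) / np.outer(sd, sd[ref_idx]) / X.shape[1]
        corr = np.nan_to_num(corr, nan=0.0)  # constant genes score 0, never error
        scores = np.abs(corr).max(axis=1)
        # "correlated with the separators but not them": drop refs up front
        keep = np.setdiff1d(np.arange(len(genes)), ref_idx)
        gs = _rank_by_score(genes[keep], scores[keep], n)
        gs.method = "correlated_with_reference"
        return gs

    return select_rate_adjusted_variable(ds, n_genes=n, tpm_cutoff=req.tpm_cutoff)


def select_rate_adjusted_variable(
    ds: Dataset,
    n_genes: int = 150,
    tpm_cutoff: float = 32.0,
    decay: float = 1.5,
    offset: float = 0.02,
) -> GeneSet:
    """Variable genes on the low-detection-rate / high-expression frontier.

    For each gene let d = fraction of cells with TPM > ``tpm_cutoff`` and
    m = mean log2(TPM) over those cells.  A gene is selected when
    d < exp(-decay * (m - b)) + offset, with the intercept b tuned by
    bisection so that exactly ``n_genes`` genes are selected (ties resolved
    in favour of larger m).  Genes never exceeding the cutoff (d = 0, m
    undefined) are excluded.  Output is ranked by m descending.
    """
    expr = ds.expr.df.to_numpy()
    above = expr > tpm_cutoff
    d = above.mean(axis=1)
    qualifying = d > 0
    if qualifying.sum() == 0:
        warnings.warn("no gene ever exceeds the TPM cutoff")
        return GeneSet(method="rate_adjusted_variable", genes=[])
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(qualifying,
                     np.nansum(np.where(above, np.log2(np.maximum(expr, 1e-12)), 0.0), axis=1)
                     / np.maximum(above.sum(axis=1), 1),
                     np.nan)

    dq, mq = d[qualifying], m[qualifying]
    names = ds.expr.genes[qualifying]
    if len(names) <= n_genes:
        if len(names) < n_genes:
            warnings.warn(f"only {len(names)} genes exceed the cutoff; returning all")
        order = np.argsort(-mq, kind="stable")
        return GeneSet(method="rate_adjusted_variable",
                       genes=[names[i] for i in order],
                       scores=[float(mq[i]) for i in order])

    def n_selected(b: float) -> int:
        return int((dq < np.exp(-decay * (mq - b)) + offset).sum())

    lo, hi = mq.min() - 50.0, mq.max() + 50.0
    for _ in range(200):  # bisect to the smallest b selecting >= n_genes
        mid = 0.5 * (lo + hi)
        if n_selected(mid) >= n_genes:
            hi = mid
        else:
            lo = mid
    selected = dq < np.exp(-decay * (mq - hi)) + offset
    idx = np.flatnonzero(selected)
    idx = idx[np.argsort(-mq[idx], kind="stable")]
    idx = idx[:n_genes]  # ties at the frontier resolved by larger m
    return GeneSet(method="rate_adjusted_variable",
                   genes=[names[i] for i in idx],
                   scores=[float(mq[i]) for i in idx])
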