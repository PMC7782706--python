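"""Cell-level quality control, expression gating, and differential expression.

QC removes cells whose unique-gene count or aligned-read count falls more
than three (unscaled) median absolute deviations below the cohort median.
DE applies the expression gate (TPM > 15 in at least five cells pooled over
the two groups), a pluggable two-sample test, Benjamini-Hochberg FDR, and
flags genes with |log2 fold difference| > 1 and FDR < 0.05.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import Dataset, GeneSet, ValidationError

logger = logging.getLogger(__name__)

#: binarization cutoff shared with the transition detector
EXPRESSED_CUTOFF_TPM = 0.6


@dataclass
class QCReport:
    """Per-cell QC metrics, the thresholds applied, and the pass verdicts."""

    metrics: pd.DataFrame  # columns: unique_gene_count, aligned_read_count, pass_*
    gene_threshold: float
    read_threshold: float
    n_mads: float
    read_metric_is_proxy: bool = False

    @property
    def passing_cells(self) -> list[str]:
        return self.metrics.index[self.metrics["pass"]].tolist()

    @property
    def failing_cells(self) -> list[str]:
        return self.metrics.index[~self.metrics["pass"]].tolist()


def mad(values: np.ndarray) -> float:
    """Unscaled median absolute deviation (no 1.4826 consistency factor)."""
    values = np.asarray(values, dtype=float)
    return float(np.median(np.abs(values - np.median(values))))


def qc_metrics(ds: Dataset) -> pd.DataFrame:
    """Derive QC metrics from a TPM matrix.

    The aligned-read count is not recoverable from TPM; total TPM mass is
    used as a stand-in and flagged as such downstream.
    """
    detected = (ds.expr.df > 0).sum(axis=0)
    mass = ds.expr.df.sum(axis=0)
    return pd.DataFrame({"unique_gene_count": detected, "aligned_read_count": mass})


def qc_filter(counts: pd.DataFrame, n_mads: float = 3.0,
              read_metric_is_proxy: bool = False) -> QCReport:
    """Flag cells more than ``n_mads`` MADs below the median on either metric.

    ``counts`` must have one row per cell and columns ``unique_gene_count``
    and ``aligned_read_count``.  A cell fails if EITHER metric is strictly
    below median - n_mads * MAD for that metric.
    """
    required = {"unique_gene_count", "aligned_read_count"}
    if not required <= set(counts.columns):
        raise ValidationError(f"counts table needs columns {sorted(required)}")
    if len(counts) < 3:
        raise ValidationError("QC thresholds undefined for fewer than 3 cells")
    out = counts[["unique_gene_count", "aligned_read_count"]].astype(float).copy()
    thresholds = {}
    for col in ("unique_gene_count", "aligned_read_count"):
        vals = out[col].to_numpy()
        thresholds[col] = float(np.median(vals)) - n_mads * mad(vals)
        out[f"pass_{col}"] = out[col] >= thresholds[col]
    out["pass"] = out["pass_unique_gene_count"] & out["pass_aligned_read_count"]
    n_fail = int((~out["pass"]).sum())
    if n_fail:
        logger.info("qc_filter: %d of %d cells fail", n_fail, len(out))
    return QCReport(
        metrics=out,
        gene_threshold=thresholds["unique_gene_count"],
        read_threshold=thresholds["aligned_read_count"],
        n_mads=n_mads,
        read_metric_is_proxy=read_metric_is_proxy,
    )


def _check_groups(ds: Dataset, group_a, group_b) -> tuple[list[str], list[str]]:
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    if not group_a or not group_b:
        raise ValidationError("both groups must be nonempty")
    missing = (set(group_a) | set(group_b)) - set(ds.cells)
    if missing:
        raise ValidationError(f"cells not in dataset: {sorted(missing)[:5]}")
    return group_a, group_b


def feature_gate(ds: Dataset, group_a, group_b,
                 min_tpm: float = 15.0, min_cells: int = 5) -> GeneSet:
    """Genes expressed at TPM strictly above ``min_tpm`` in at least
    ``min_cells`` cells pooled over the two groups."""
    group_a, group_b = _check_groups(ds, group_a, group_b)
    pooled = ds.expr.df[group_a + group_b]
    n_above = (pooled > min_tpm).sum(axis=1)
    kept = n_above.index[n_above >= min_cells].tolist()
    return GeneSet(method=f"feature_gate(tpm>{min_tpm}, n>={min_cells})", genes=kept)


@dataclass
class DETable:
    """Per-gene group means, log2 fold difference, p, FDR, and the DE flag."""

    df: pd.DataFrame
    test: str
    epsilon_tpm: float

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def de_genes(self) -> list[str]:
        return self.df.loc[self.df["de_flag"], "gene"].tolist()


def differential_expression(
    ds: Dataset,
    group_a,
    group_b,
    test: str = "rank_sum",
    min_tpm: float = 15.0,
    min_cells: int = 5,
    fold_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    epsilon_tpm: float = 1.0,
) -> DETable:
    """Two-group differential expression with the standard gating rules.

    Genes pass :func:`feature_gate` first.  The two-sample test is pluggable:
    ``rank_sum`` (two-sided Wilcoxon rank-sum on log2(TPM+1), default) or
    ``welch_log`` (Welch's t on log2(TPM+1)).  Fold difference uses a 1 TPM
    pseudo-value: logFD = log2((mean_a + eps) / (mean_b + eps)).  A gene is
    flagged DE iff |logFD| > log2(fold_threshold) and BH FDR < fdr_threshold.
    """
    group_a, group_b = _check_groups(ds, group_a, group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValidationError("each group needs >= 3 cells for the two-sample test")
    gated = feature_gate(ds, group_a, group_b, min_tpm=min_tpm, min_cells=min_cells)
    if len(gated) == 0:
        return DETable(
            pd.DataFrame(columns=["gene", "mean_a", "mean_b", "logFD", "p", "fdr", "de_flag"]),
            test, epsilon_tpm)
    sub = ds.expr.df.loc[gated.genes]
    a = sub[group_a].to_numpy()
    b = sub[group_b].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    logfd = np.log2((mean_a + epsilon_tpm) / (mean_b + epsilon_tpm))
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    if test == "rank_sum":
        res = stats.mannwhitneyu(la, lb, axis=1, alternative="two-sided")
        pvals = np.asarray(res.pvalue, dtype=float)
    elif test == "welch_log":
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    else:
        raise ValueError(f"unknown test {test!r}")
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance ties
    fdr = multipletests(pvals, method="fdr_bh")[1]
    de_flag = (np.abs(logfd) > np.log2(fold_threshold)) & (fdr < fdr_threshold)
    df = pd.DataFrame({
        "gene": gated.genes, "mean_a": mean_a, "mean_b": mean_b,
        "logFD": logfd, "p": pvals, "fdr": fdr, "de_flag": de_flag,
    }).sort_values(["fdr", "p"], kind="stable").reset_index(drop=True)
    return DETable(df, test, epsilon_tpm)


def cam_expression_filter(ds: Dataset, cam_genes: GeneSet, min_cells: int = 3,
                          cutoff_tpm: float = EXPRESSED_CUTOFF_TPM) -> GeneSet:
    """CAM genes expressed (TPM > cutoff) in at least ``min_cells`` cells."""
    present = [g for g in cam_genes if g in set(ds.expr.genes)]
    absent = [g for g in cam_genes if g not in set(ds.expr.genes)]
    if absent:
        logger.info("cam_expression_filter: %d CAM genes absent from matrix", len(absent))
    if not present:
        return GeneSet(method="cam_expression_filter", genes=[])
    n_expr = (ds.expr.df.loc[present] > cutoff_tpm).sum(axis=1)
    kept = [g for g in present if n_expr[g] >= min_cells]
    return GeneSet(method="cam_expression_filter", genes=kept)
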