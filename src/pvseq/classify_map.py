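"""Balanced random-forest classification, SVM-RFE, confusion matrices, and
correlation-kNN mapping onto a reference embedding.

The balanced protocol: per repeat, the larger class is randomly downsampled
to the size of the smaller one, 80% of the remaining cells train a fresh
100-tree forest, and accuracy is scored on the held-out 20%; the whole
procedure is repeated (default 100x) and averaged.  With equal class sizes,
chance accuracy is 50%, which anchors the interpretation of the score.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import LinearSVC

from .data import Dataset, GeneSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ClassificationResult:
    overall_accuracy: float
    per_cell_accuracy: dict[str, float]
    per_repeat_accuracy: np.ndarray
    n_repeats: int
    n_trees: int
    train_fraction: float
    seed: int | None
    rf_params: dict = field(default_factory=dict)


def balanced_rf_accuracy(
    ds: Dataset,
    labels,
    n_trees: int = 100,
    n_repeats: int = 100,
    train_fraction: float = 0.8,
    seed: int | None = None,
) -> ClassificationResult:
    """Class-balanced random-forest accuracy over repeated resampling.

    ``labels`` is a per-cell binary label vector (aligned with ds.cells).
    Each repeat independently re-draws the downsampling and the train/test
    split (stratified so both classes appear on both sides).  Per-cell
    accuracy is the fraction of a cell's test-set appearances that were
    classified correctly.
    """
    y = np.asarray(labels)
    if len(y) != ds.n_cells:
        raise ValidationError("labels length must equal number of cells")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError(f"binary labels required, got {len(classes)} classes")
    idx_by_class = [np.flatnonzero(y == c) for c in classes]
    m = min(len(i) for i in idx_by_class)
    if m < 5:
        raise ValidationError("each class needs at least 5 cells")

    X = np.log2(ds.expr.df.to_numpy().T + 1.0)  # cells x genes
    cell_ids = list(ds.cells)
    rng = np.random.default_rng(seed)
    correct = np.zeros(ds.n_cells)
    appearances = np.zeros(ds.n_cells)
    per_repeat = np.empty(n_repeats)

    n_train_per_class = max(int(round(train_fraction * m)), 1)
    if n_train_per_class >= m:
        n_train_per_class = m - 1
    for rep in range(n_repeats):
        train_idx, test_idx = [], []
        for idx in idx_by_class:
            pick = rng.choice(idx, size=m, replace=False)  # downsample larger class
            pick = rng.permutation(pick)
            train_idx.append(pick[:n_train_per_class])
            test_idx.append(pick[n_train_per_class:])
        train = np.concatenate(train_idx)
        test = np.concatenate(test_idx)
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(X[train], y[train])
        pred = forest.predict(X[test])
        hits = pred == y[test]
        per_repeat[rep] = hits.mean()
        correct[test] += hits
        appearances[test] += 1

    per_cell = {cell_ids[i]: float(correct[i] / appearances[i])
                for i in range(ds.n_cells) if appearances[i] > 0}
    return ClassificationResult(
        overall_accuracy=float(per_repeat.mean()),
        per_cell_accuracy=per_cell,
        per_repeat_accuracy=per_repeat,
        n_repeats=n_repeats,
        n_trees=n_trees,
        train_fraction=train_fraction,
        seed=seed,
        rf_params=forest.get_params(),
    )


def svm_rfe(
    ds: Dataset,
    labels,
    n_keep: int = 50,
    drop_fraction_per_round: float = 0.1,
    seed: int | None = None,
) -> GeneSet:
    """Top marker genes by linear-SVM recursive feature elimination.

    A linear max-margin classifier is trained on log2(TPM+1); genes are
    ranked by absolute weight (max across one-vs-rest weights for more than
    two classes), the lowest-ranked fraction is dropped, and the loop repeats
    until ``n_keep`` genes remain.  The primal squared-hinge solver makes the
    procedure deterministic.
    """
    y = np.asarray(labels)
    if len(y) != ds.n_cells:
        raise ValidationError("labels length must equal number of cells")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 3:
        raise ValidationError("need >= 2 classes with >= 3 cells each")
    genes = list(ds.expr.genes)
    if n_keep >= len(genes):
        logger.warning("svm_rfe: n_keep >= gene count; returning all genes unranked")
        return GeneSet(method="svm_rfe", genes=genes)
    X_full = ds.expr.log2p1().to_numpy().T
    active = np.arange(len(genes))
    while len(active) > n_keep:
        clf = LinearSVC(dual=False, max_iter=10000)
        clf.fit(X_full[:, active], y)
        weights = np.abs(clf.coef_)
        importance = weights.max(axis=0) if weights.shape[0] > 1 else np.abs(weights[0])
        n_drop = max(int(len(active) * drop_fraction_per_round), 1)
        n_drop = min(n_drop, len(active) - n_keep)
        order = np.argsort(importance, kind="stable")
        active = np.delete(active, order[:n_drop])
    clf = LinearSVC(dual=False, max_iter=10000)
    clf.fit(X_full[:, active], y)
    weights = np.abs(clf.coef_)
    importance = weights.max(axis=0) if weights.shape[0] > 1 else np.abs(weights[0])
    order = np.argsort(-importance, kind="stable")
    return GeneSet(method="svm_rfe",
                   genes=[genes[active[i]] for i in order],
                   scores=[float(importance[i]) for i in order])


def confusion_matrix(labels_a: pd.Series, labels_b: pd.Series,
                     order_a=None, order_b=None) -> pd.DataFrame:
    """Co-occurrence counts between two labelings of the same cells.

    Rows follow ``labels_a`` (e.g. morphological types), columns
    ``labels_b`` (e.g. transcriptomic types); declared orders are honoured.
    """
    labels_a, labels_b = pd.Series(labels_a), pd.Series(labels_b)
    if set(labels_a.index) != set(labels_b.index):
        raise ValidationError("both labelings must cover the same cells")
    labels_b = labels_b.loc[labels_a.index]
    table = pd.crosstab(labels_a, labels_b)
    order_a = list(order_a) if order_a is not None else sorted(table.index)
    order_b = list(order_b) if order_b is not None else sorted(table.columns)
    return table.reindex(index=order_a, columns=order_b, fill_value=0)


@dataclass
class EmbeddingReference:
    """A reference expression matrix with 2-D embedding coordinates."""

    expr: pd.DataFrame  # genes x reference cells, TPM
    coords: pd.DataFrame  # reference cells x (x, y)
    genes: list[str]
    k: int = 10

    def __post_init__(self):
        if not np.isfinite(self.coords.to_numpy()).all():
            raise ValidationError("reference coordinates must be finite")
        if not 1 <= self.k <= self.coords.shape[0]:
            raise ValidationError("k must be in [1, reference size]")


def knn_map(query, ref: EmbeddingReference, method: str = "pearson") -> pd.DataFrame:
    """Map query cells onto a reference embedding by correlation kNN.

    Distance = 1 - correlation of log2(TPM+1) over ``ref.genes`` (Pearson by
    default; ``method="spearman"`` rank-transforms first, which is robust to
    depth differences between query and reference).  Ties at the k-th
    neighbor break by reference cell order; the mapped position is the
    component-wise median of the k neighbors' coordinates.  Query cells with
    zero variance on the gene set get NaN coordinates and a note, the run
    continues.
    """
    query_df = query.df if hasattr(query, "df") else query
    missing = [g for g in ref.genes if g not in query_df.index or g not in ref.expr.index]
    if missing:
        raise ValidationError(f"genes absent from query or reference: {missing[:5]}")
    q = np.log2(query_df.loc[ref.genes].to_numpy().T + 1.0)  # query cells x genes
    r = np.log2(ref.expr.loc[ref.genes].to_numpy().T + 1.0)  # ref cells x genes
    if method == "spearman":
        q = pd.DataFrame(q).rank(axis=1).to_numpy()
        r = pd.DataFrame(r).rank(axis=1).to_numpy()
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")

    qc = q - q.mean(axis=1, keepdims=True)
    rc = r - r.mean(axis=1, keepdims=True)
    q_sd = qc.std(axis=1)
    r_sd = rc.std(axis=1)
    coords = ref.coords.to_numpy()
    out = np.full((q.shape[0], 2), np.nan)
    notes = []
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (qc @ rc.T) / q.shape[1] / np.outer(q_sd, r_sd)
    for i in range(q.shape[0]):
        if q_sd[i] == 0 or np.isnan(corr[i]).all():
            notes.append("constant expression on gene set; correlation undefined")
            continue
        dist = 1.0 - corr[i]
        order = np.lexsort((np.arange(len(dist)), dist))  # tie-break by ref order
        nn = order[: ref.k]
        out[i] = np.median(coords[nn], axis=0)
        notes.append("")
    result = pd.DataFrame(out, index=list(query_df.columns), columns=["x", "y"])
    result["note"] = notes
    return result
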