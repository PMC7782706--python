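"""Balanced random-forest protocol, SVM-RFE, confusion matrix, kNN mapping."""
import numpy as np
import pandas as pd
import pytest

from pvseq.classify_map import (
    EmbeddingReference,
    balanced_rf_accuracy,
    confusion_matrix,
    knn_map,
    svm_rfe,
)
from pvseq.data import ValidationError

from conftest import make_dataset


def _separable(rng, n_per_class=15, n_noise=40):
    tpm = rng.gamma(2.0, 5.0, size=(n_noise + 1, 2 * n_per_class))
    tpm[0, :n_per_class] = 100.0
    tpm[0, n_per_class:] = 0.0
    labels = [0] * n_per_class + [1] * n_per_class
    return make_dataset(tpm), labels


class TestBalancedRF:
    def test_perfect_separator_gives_accuracy_one(self, rng):
        ds, labels = _separable(rng, n_noise=10)
        res = balanced_rf_accuracy(ds, labels, n_repeats=10, seed=0)
        assert res.overall_accuracy == 1.0
        assert all(v == 1.0 for v in res.per_cell_accuracy.values())

    def test_deterministic_given_seed(self, rng):
        ds, labels = _separable(rng, n_per_class=8, n_noise=10)
        r1 = balanced_rf_accuracy(ds, labels, n_repeats=5, seed=42)
        r2 = balanced_rf_accuracy(ds, labels, n_repeats=5, seed=42)
        assert r1.overall_accuracy == r2.overall_accuracy
        np.testing.assert_array_equal(r1.per_repeat_accuracy, r2.per_repeat_accuracy)

    def test_label_permutation_converges_to_chance(self, rng):
        # information-free labels -> ~50% on average over fresh permutations
        # (one fixed permutation keeps cohort-level spurious association)
        tpm = rng.gamma(2.0, 5.0, size=(100, 60))
        ds = make_dataset(tpm)
        accs = []
        for rep in range(8):
            labels = rng.permutation([0] * 30 + [1] * 30)
            res = balanced_rf_accuracy(ds, labels, n_repeats=12, seed=rep)
            accs.append(res.overall_accuracy)
        assert 0.45 <= np.mean(accs) <= 0.55

    def test_repeat_level_se_is_tight_at_100_repeats(self, rng):
        tpm = rng.gamma(2.0, 5.0, size=(60, 60))
        ds = make_dataset(tpm)
        res = balanced_rf_accuracy(ds, [0] * 30 + [1] * 30, n_repeats=100, seed=7)
        se = res.per_repeat_accuracy.std(ddof=1) / 10.0
        assert se <= 0.02

    def test_small_class_rejected(self, rng):
        ds, _ = _separable(rng, n_per_class=6, n_noise=5)
        with pytest.raises(ValidationError, match="at least 5"):
            balanced_rf_accuracy(ds, [0] * 9 + [1] * 3, n_repeats=2)

    def test_non_binary_labels_rejected(self, rng):
        ds, _ = _separable(rng, n_per_class=6, n_noise=5)
        with pytest.raises(ValidationError, match="binary"):
            balanced_rf_accuracy(ds, [0, 1, 2] * 4, n_repeats=2)


class TestSvmRfe:
    def test_planted_separator_survives_elimination(self, rng):
        ds, labels = _separable(rng, n_per_class=12, n_noise=200)
        gs = svm_rfe(ds, labels, n_keep=50)
        assert "g0" in gs.genes and len(gs) == 50

    def test_n_keep_equal_to_gene_count_is_identity(self, rng):
        ds, labels = _separable(rng, n_per_class=6, n_noise=9)
        gs = svm_rfe(ds, labels, n_keep=10)
        assert set(gs.genes) == {f"g{i}" for i in range(10)}

    def test_duplicated_separators_do_not_crash(self, rng):
        tpm = rng.gamma(2.0, 5.0, size=(12, 20))
        tpm[0, :10], tpm[0, 10:] = 100.0, 0.0
        tpm[1] = tpm[0]  # collinear twin
        ds = make_dataset(tpm)
        gs = svm_rfe(ds, [0] * 10 + [1] * 10, n_keep=5)
        assert len(gs) == 5
        assert {"g0", "g1"} & set(gs.genes)


class TestConfusionMatrix:
    def test_identical_labels_are_diagonal(self):
        cells = [f"c{i}" for i in range(10)]
        labels = pd.Series(["x"] * 6 + ["y"] * 4, index=cells)
        cm = confusion_matrix(labels, labels)
        assert cm.loc["x", "x"] == 6 and cm.loc["y", "y"] == 4
        assert cm.loc["x", "y"] == 0 and cm.loc["y", "x"] == 0

    def test_row_sums_match_class_sizes(self, rng):
        cells = [f"c{i}" for i in range(30)]
        a = pd.Series(rng.choice(["p", "q"], 30), index=cells)
        b = pd.Series(rng.choice(["u", "v", "w"], 30), index=cells)
        cm = confusion_matrix(a, b)
        assert cm.sum(axis=1).to_dict() == a.value_counts().to_dict()
        assert cm.to_numpy().sum() == 30

    def test_single_cell(self):
        a = pd.Series({"c0": "x"})
        cm = confusion_matrix(a, pd.Series({"c0": "y"}))
        assert cm.loc["x", "y"] == 1

    def test_mismatched_cells_rejected(self):
        with pytest.raises(ValidationError):
            confusion_matrix(pd.Series({"c0": "x"}), pd.Series({"c1": "y"}))


def _reference(rng, n_genes=20, n_ref=6):
    genes = [f"g{i}" for i in range(n_genes)]
    expr = pd.DataFrame(rng.gamma(2.0, 10.0, size=(n_genes, n_ref)),
                        index=genes, columns=[f"r{i}" for i in range(n_ref)])
    coords = pd.DataFrame({"x": rng.normal(size=n_ref), "y": rng.normal(size=n_ref)},
                          index=expr.columns)
    return expr, coords, genes


class TestKnnMap:
    def test_identical_query_maps_onto_its_reference_cell(self, rng):
        expr, coords, genes = _reference(rng)
        ref = EmbeddingReference(expr=expr, coords=coords, genes=genes, k=1)
        query = expr[["r3"]].rename(columns={"r3": "q"})
        out = knn_map(query, ref)
        assert out.loc["q", "x"] == coords.loc["r3", "x"]
        assert out.loc["q", "y"] == coords.loc["r3", "y"]

    def test_componentwise_median_of_three_neighbors(self, rng):
        genes = [f"g{i}" for i in range(10)]
        base = rng.gamma(2.0, 10.0, size=10)
        # three reference cells nearly identical to the query, far-away rest
        ref_expr = pd.DataFrame(
            {f"r{i}": base * (1 + 0.001 * i) for i in range(3)}
            | {f"far{i}": rng.gamma(2.0, 10.0, size=10) for i in range(4)},
            index=genes)
        coords = pd.DataFrame(
            [[0, 0], [0, 2], [4, 6], [99, 99], [99, 99], [99, 99], [99, 99]],
            index=ref_expr.columns, columns=["x", "y"], dtype=float)
        ref = EmbeddingReference(expr=ref_expr, coords=coords, genes=genes, k=3)
        query = pd.DataFrame({"q": base}, index=genes)
        out = knn_map(query, ref)
        assert (out.loc["q", "x"], out.loc["q", "y"]) == (0.0, 2.0)

    def test_constant_query_flagged_not_fatal(self, rng):
        expr, coords, genes = _reference(rng)
        ref = EmbeddingReference(expr=expr, coords=coords, genes=genes, k=2)
        query = pd.DataFrame({"flat": np.ones(len(genes)), "ok": expr["r0"]},
                             index=genes)
        out = knn_map(query, ref)
        assert np.isnan(out.loc["flat", "x"]) and out.loc["flat", "note"]
        assert np.isfinite(out.loc["ok", "x"])

    def test_mapped_point_inside_neighbor_bounding_box(self, rng):
        expr, coords, genes = _reference(rng, n_ref=12)
        ref = EmbeddingReference(expr=expr, coords=coords, genes=genes, k=5)
        query = pd.DataFrame(rng.gamma(2.0, 10.0, size=(len(genes), 8)),
                             index=genes,
                             columns=[f"q{i}" for i in range(8)])
        out = knn_map(query, ref)
        for _, row in out.iterrows():
            assert coords["x"].min() <= row["x"] <= coords["x"].max()
            assert coords["y"].min() <= row["y"] <= coords["y"].max()
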