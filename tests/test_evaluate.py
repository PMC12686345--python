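"""Splits, confusion metrics, ROC/AUC, cross-validation and band statistics."""

import dataclasses
import itertools

import numpy as np
import pytest
from scipy import stats

from ramancaf import (
    ConfusionMatrix,
    SplitSpec,
    band_statistics,
    classification_metrics,
    confusion_matrix,
    cross_validate,
    f1_from_precision_recall,
    preprocess_dataset,
    reconstruct_totals,
    roc_ovr,
    split_dataset,
)
from ramancaf.evaluate import auc_trapezoid, _binary_roc


class TestSplitDataset:
    def test_spectrum_mode_sizes(self, small_sim_dataset):
        train, test = split_dataset(small_sim_dataset, SplitSpec(test_fraction=0.3))
        assert test.n_spectra == round(0.3 * small_sim_dataset.n_spectra)
        assert train.n_spectra + test.n_spectra == small_sim_dataset.n_spectra
        # stratification: per-class proportions preserved
        for cls in small_sim_dataset.class_order:
            n_cls = (small_sim_dataset.labels == cls).sum()
            assert (test.labels == cls).sum() == round(0.3 * n_cls)

    def test_cell_mode_keeps_cells_whole(self, small_sim_dataset):
        train, test = split_dataset(
            small_sim_dataset, SplitSpec(test_fraction=0.34, mode="cell")
        )
        assert set(train.cell_ids).isdisjoint(set(test.cell_ids))

    def test_deterministic_given_seed(self, small_sim_dataset):
        a = split_dataset(small_sim_dataset, SplitSpec(seed=5))
        b = split_dataset(small_sim_dataset, SplitSpec(seed=5))
        assert list(a[1].cell_ids) == list(b[1].cell_ids)
        np.testing.assert_array_equal(a[1].matrix, b[1].matrix)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(test_fraction=1.5)

    def test_single_cell_class_rejected_in_cell_mode(self, tiny_dataset):
        with pytest.raises(ValueError):
            split_dataset(tiny_dataset, SplitSpec(mode="cell"))


class TestConfusionMatrix:
    def test_hand_counted_example(self):
        cm = confusion_matrix(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])
        assert cm.total == 3

    def test_perfect_prediction_is_diagonal(self):
        truth = ["A", "B", "C"] * 4
        cm = confusion_matrix(truth, truth, ["A", "B", "C"])
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        assert np.trace(cm.counts) == 12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["A"], ["A", "B"], ["A", "B"])


class TestClassificationMetrics:
    def test_perfect_matrix(self):
        cm = ConfusionMatrix(counts=np.eye(3, dtype=int) * 10, class_order=("a", "b", "c"))
        m = classification_metrics(cm)
        assert m.accuracy == 1.0
        np.testing.assert_array_equal(m.precision, 1.0)
        np.testing.assert_array_equal(m.recall, 1.0)
        np.testing.assert_array_equal(m.f1, 1.0)

    @pytest.mark.parametrize(
        "precision,recall,f1_4dp",
        [
            (0.9906, 0.8474, 0.9134),
            (0.9722, 0.9775, 0.9748),
            (0.9181, 0.9873, 0.9514),
        ],
    )
    def test_f1_harmonic_mean_identity(self, precision, recall, f1_4dp):
        """Published per-class precision/recall reproduce the published F1."""
        assert round(f1_from_precision_recall(precision, recall), 4) == f1_4dp

    def test_micro_recall_equals_accuracy(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            counts = rng.integers(0, 30, size=(3, 3))
            counts[0, 0] += 1  # non-empty
            cm = ConfusionMatrix(counts=counts, class_order=("a", "b", "c"))
            m = classification_metrics(cm)
            micro_recall = np.trace(counts) / counts.sum()
            assert m.accuracy == pytest.approx(micro_recall, abs=1e-12)

    def test_zero_column_flagged_not_crashed(self):
        cm = ConfusionMatrix(
            counts=np.array([[3, 0], [2, 0]]), class_order=("a", "b")
        )
        m = classification_metrics(cm)
        assert m.precision[1] == 0.0
        assert "b" in m.undefined_precision

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(counts=np.zeros((2, 2), int), class_order=("a", "b"))
        with pytest.raises(ValueError):
            classification_metrics(cm)


class TestReconstructTotals:
    def test_published_table_reconstruction(self):
        """Diagonal counts / recall and / precision give the same grand total."""
        out = reconstruct_totals(
            correct=[1377, 2653, 2880],
            precision=[0.9906, 0.9722, 0.9181],
            recall=[0.8474, 0.9775, 0.9873],
        )
        assert out["grand_total_by_recall"] == out["grand_total_by_precision"] == 7256
        assert round(out["accuracy"], 2) == 0.95


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([[0.9], [0.8], [0.7], [0.1]])
        truth = ["p", "p", "n", "n"]
        roc = roc_ovr(scores, truth, ["p"])
        assert roc.auc["p"] == 1.0

    def test_constant_scores_give_half(self):
        scores = np.full((6, 1), 0.5)
        truth = ["p", "n", "p", "n", "p", "n"]
        roc = roc_ovr(scores, truth, ["p"])
        assert roc.auc["p"] == pytest.approx(0.5)

    def test_three_of_four_concordant_pairs(self):
        scores = np.array([[0.9], [0.4], [0.6], [0.1]])
        truth = ["p", "p", "n", "n"]
        roc = roc_ovr(scores, truth, ["p"])
        assert roc.auc["p"] == pytest.approx(0.75)

    def test_curves_monotone(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(40, 2))
        truth = list(rng.choice(["a", "b"], size=40))
        roc = roc_ovr(scores, truth, ["a", "b"])
        for cls in ("a", "b"):
            assert np.all(np.diff(roc.fpr[cls]) >= 0)
            assert np.all(np.diff(roc.tpr[cls]) >= 0)

    def test_absent_class_reported_absent(self):
        scores = np.zeros((3, 2))
        roc = roc_ovr(scores, ["a", "a", "a"], ["a", "b"])
        assert "b" not in roc.auc and "a" not in roc.auc  # 'a' fills truth entirely

    def test_auc_equals_concordant_pair_count(self):
        """Brute-force Mann-Whitney oracle on small random instances."""
        rng = np.random.default_rng(2)
        for m in (5, 17, 50):
            scores = np.round(rng.normal(size=m), 1)  # coarse grid forces ties
            positive = rng.random(m) < 0.4
            if positive.sum() in (0, m):
                positive[0] = ~positive[0]
            fpr, tpr = _binary_roc(scores, positive)
            auc = auc_trapezoid(fpr, tpr)
            pairs = concordant = 0.0
            for i, j in itertools.product(
                np.flatnonzero(positive), np.flatnonzero(~positive)
            ):
                pairs += 1
                if scores[i] > scores[j]:
                    concordant += 1
                elif scores[i] == scores[j]:
                    concordant += 0.5
            assert auc == pytest.approx(concordant / pairs, abs=1e-12)


class TestCrossValidate:
    def test_folds_partition_dataset(self, small_sim_dataset):
        processed = preprocess_dataset(small_sim_dataset)
        report = cross_validate(processed, k=5, seed=3)
        folds = report.fold_assignment
        assert folds.min() == 0 and folds.max() == 4
        assert folds.size == processed.n_spectra
        counts = np.bincount(folds)
        assert counts.sum() == processed.n_spectra
        assert counts.max() - counts.min() <= len(processed.class_order) * 1

    def test_cell_mode_never_splits_a_cell(self, small_sim_dataset):
        processed = preprocess_dataset(small_sim_dataset)
        report = cross_validate(processed, k=3, mode="cell", seed=1)
        cells = np.asarray([str(c) for c in processed.cell_ids])
        for cell in np.unique(cells):
            assert len(set(report.fold_assignment[cells == cell])) == 1

    def test_separable_data_scores_perfectly(self):
        """Widely separated classes must give mean CV accuracy 1.0."""
        from ramancaf import SpectralDataset, WavenumberGrid

        rng = np.random.default_rng(4)
        grid = WavenumberGrid(np.arange(400.0, 410.0))
        n = 60
        labels = np.repeat(["a", "b", "c"], n // 3)
        # classes at triangle vertices: no masking of the middle class
        X = rng.normal(0.0, 0.01, size=(n, 10))
        X[:, 0] += 5.0 * (labels == "b")
        X[:, 1] += 5.0 * (labels == "c")
        ds = SpectralDataset(
            grid=grid,
            matrix=X,
            labels=labels.astype(object),
            cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
            class_order=("a", "b", "c"),
        )
        report = cross_validate(ds, k=5, n_components=2, seed=0)
        assert report.mean_accuracy == 1.0

    def test_deterministic_given_seed(self, small_sim_dataset):
        processed = preprocess_dataset(small_sim_dataset)
        a = cross_validate(processed, k=4, seed=9)
        b = cross_validate(processed, k=4, seed=9)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        assert a.mean_accuracy == b.mean_accuracy

    def test_k_larger_than_class_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            cross_validate(tiny_dataset, k=5)


class TestBandStatistics:
    @pytest.fixture()
    def two_group_dataset(self):
        from ramancaf import SpectralDataset, WavenumberGrid

        grid = WavenumberGrid(np.array([500.0, 600.0]))
        matrix = np.array([[1.0, 0], [2.0, 0], [3.0, 0], [4.0, 0], [5.0, 0], [6.0, 0]])
        return SpectralDataset(
            grid=grid,
            matrix=matrix,
            labels=np.array(["A"] * 3 + ["B"] * 3, dtype=object),
            cell_ids=np.array(["c1"] * 3 + ["c2"] * 3, dtype=object),
            class_order=("A", "B"),
        )

    def test_pooled_t_test_hand_value(self, two_group_dataset):
        """{1,2,3} vs {4,5,6}: t = -3.674, two-sided p ~= 0.0213 at df 4."""
        bs = band_statistics(two_group_dataset, 500.0, half_width=0.0)
        assert bs.mean == {"A": 2.0, "B": 5.0}
        assert bs.sd == {"A": 1.0, "B": 1.0}
        t, p = bs.t_tests[("A", "B")]
        assert t == pytest.approx(-3.6742, abs=1e-4)
        assert p == pytest.approx(2 * stats.t.cdf(-3.6742346, df=4), abs=1e-4)
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_identical_groups(self):
        from ramancaf import SpectralDataset, WavenumberGrid

        grid = WavenumberGrid(np.array([500.0, 600.0]))
        matrix = np.array([[v, 0.0] for v in (1.0, 2.0, 3.0, 1.0, 2.0, 3.0)])
        ds = SpectralDataset(
            grid=grid,
            matrix=matrix,
            labels=np.array(["A"] * 3 + ["B"] * 3, dtype=object),
            cell_ids=np.array(["c1"] * 3 + ["c2"] * 3, dtype=object),
            class_order=("A", "B"),
        )
        t, p = band_statistics(ds, 500.0, half_width=0.0).t_tests[("A", "B")]
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_degenerate_zero_variance_reported_none(self):
        from ramancaf import SpectralDataset, WavenumberGrid

        grid = WavenumberGrid(np.array([500.0, 600.0]))
        matrix = np.array([[2.0, 0.0]] * 4)
        ds = SpectralDataset(
            grid=grid,
            matrix=matrix,
            labels=np.array(["A", "A", "B", "B"], dtype=object),
            cell_ids=np.array(["c1", "c1", "c2", "c2"], dtype=object),
            class_order=("A", "B"),
        )
        assert band_statistics(ds, 500.0, half_width=0.0).t_tests[("A", "B")] is None

    def test_band_outside_grid_rejected(self, two_group_dataset):
        with pytest.raises(ValueError):
            band_statistics(two_group_dataset, 3000.0)

    def test_lipid_band_class_ordering_on_synthetic_data(self, small_sim_dataset):
        # with the reduced 3-cell design only the largest contrast is stable
        processed = preprocess_dataset(small_sim_dataset)
        bs = band_statistics(processed, 2896.0)
        assert bs.mean["HPaSC_iCAF"] > bs.mean["HPaSC_myCAF"]
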