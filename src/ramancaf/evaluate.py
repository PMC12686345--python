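"""Classification evaluation: splits, confusion matrices, ROC/AUC, CV, band statistics.

Implements the evaluation protocol of the classification study: a stratified
70/30 train/test split (at the spectrum level by default, with a cell-level
mode that keeps all spectra of a cell on one side), confusion matrix with
per-class precision/recall/F1 and overall accuracy, one-vs-rest ROC curves
with trapezoidal AUC, stratified k-fold cross-validation, and per-band
box-plot statistics with pairwise two-sample t-tests.

Spectrum-level splitting mirrors the original protocol but shares cells
between train and test, so its accuracy is an upper-bound estimate; cell
mode is the honest generalization test and is recommended for real use.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .plsda import classify, fit_plsda_dataset, predict_response
from .spectral import SpectralDataset

__all__ = [
    "SplitSpec",
    "ConfusionMatrix",
    "ClassMetrics",
    "ROCResult",
    "CVReport",
    "BandStats",
    "split_dataset",
    "confusion_matrix",
    "classification_metrics",
    "f1_from_precision_recall",
    "reconstruct_totals",
    "roc_ovr",
    "auc_trapezoid",
    "cross_validate",
    "band_statistics",
]


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.3
    mode: str = "spectrum"  # or "cell"
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.mode not in ("spectrum", "cell"):
            raise ValueError("mode must be 'spectrum' or 'cell'")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(
    dataset: SpectralDataset, spec: SplitSpec = SplitSpec()
) -> tuple[SpectralDataset, SpectralDataset]:
    """Deterministic stratified train/test split.

    ``spectrum`` mode samples rows within each class; ``cell`` mode assigns
    whole cells to one side only, so no cell id appears in both partitions.
    """
    rng = np.random.default_rng(spec.seed)
    labels = dataset.labels
    test_idx: list[np.ndarray] = []
    for cls in dataset.class_order:
        rows = np.flatnonzero(labels == cls)
        if rows.size == 0:
            continue
        if spec.mode == "spectrum":
            if rows.size < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 spectra")
            n_test = min(max(_round_half_up(rows.size * spec.test_fraction), 1), rows.size - 1)
            chosen = rng.permutation(rows)[:n_test]
        else:
            cells = np.array(sorted({str(c) for c in dataset.cell_ids[rows]}))
            if cells.size < 2:
                raise ValueError(
                    f"class {cls!r} has a single cell; cell-mode split impossible"
                )
            n_test = min(max(_round_half_up(cells.size * spec.test_fraction), 1), cells.size - 1)
            test_cells = set(rng.permutation(cells)[:n_test])
            chosen = rows[
                np.asarray([str(c) in test_cells for c in dataset.cell_ids[rows]])
            ]
        test_idx.append(chosen)
    test_rows = np.sort(np.concatenate(test_idx))
    mask = np.zeros(dataset.n_spectra, dtype=bool)
    mask[test_rows] = True
    return dataset.subset(~mask), dataset.subset(mask)


# ---------------------------------------------------------------------------
# Confusion matrix and derived metrics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConfusionMatrix:
    """K x K counts; rows are the true class, columns the predicted class."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclasses.dataclass
class ClassMetrics:
    class_order: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    undefined_precision: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                cls: {
                    "precision": float(self.precision[k]),
                    "recall": float(self.recall[k]),
                    "f1": float(self.f1[k]),
                }
                for k, cls in enumerate(self.class_order)
            },
            "undefined_precision": list(self.undefined_precision),
        }


def confusion_matrix(
    truth: Sequence[str], predicted: Sequence[str], class_order: Sequence[str]
) -> ConfusionMatrix:
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    index = {c: k for k, c in enumerate(class_order)}
    K = len(class_order)
    counts = np.zeros((K, K), dtype=int)
    for t, p in zip(truth, predicted):
        if t not in index or p not in index:
            raise ValueError(f"label outside class_order: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order))


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def classification_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    counts = cm.counts
    if counts.size == 0 or counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts).astype(float)
    colsum = counts.sum(axis=0).astype(float)
    rowsum = counts.sum(axis=1).astype(float)
    undefined = tuple(
        cls for k, cls in enumerate(cm.class_order) if colsum[k] == 0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(colsum > 0, diag / np.where(colsum > 0, colsum, 1), 0.0)
        recall = np.where(rowsum > 0, diag / np.where(rowsum > 0, rowsum, 1), 0.0)
    f1 = np.array(
        [f1_from_precision_recall(p, r) for p, r in zip(precision, recall)]
    )
    return ClassMetrics(
        class_order=cm.class_order,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=float(diag.sum() / counts.sum()),
        undefined_precision=undefined,
    )


def reconstruct_totals(
    correct: Sequence[float], precision: Sequence[float], recall: Sequence[float]
) -> dict:
    """Reconstruct per-class set sizes from published diagonal counts.

    Given the diagonal (correctly classified) counts plus per-class precision
    and recall, the true-class sizes are ``correct / recall`` and the
    predicted-class sizes ``correct / precision``.  Both routes must sum to
    the same grand total; the overall accuracy is the diagonal sum over it.
    """
    correct = np.asarray(correct, dtype=float)
    precision = np.asarray(precision, dtype=float)
    recall = np.asarray(recall, dtype=float)
    truth_sizes = np.round(correct / recall).astype(int)
    predicted_sizes = np.round(correct / precision).astype(int)
    return {
        "truth_sizes": truth_sizes,
        "predicted_sizes": predicted_sizes,
        "grand_total_by_recall": int(truth_sizes.sum()),
        "grand_total_by_precision": int(predicted_sizes.sum()),
        "accuracy": float(correct.sum() / truth_sizes.sum()),
    }


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ROCResult:
    class_order: tuple[str, ...]
    fpr: dict[str, np.ndarray]
    tpr: dict[str, np.ndarray]
    auc: dict[str, float]  # classes absent from truth are absent here

    @property
    def macro_auc(self) -> float:
        return float(np.mean([self.auc[c] for c in self.class_order if c in self.auc]))


def _binary_roc(scores: np.ndarray, positive: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC points from continuous scores; ties grouped at one threshold."""
    order = np.argsort(-scores, kind="stable")
    scores, positive = scores[order], positive[order]
    distinct = np.flatnonzero(np.diff(scores)) if scores.size > 1 else np.array([], int)
    cut = np.r_[distinct, scores.size - 1]
    tps = np.cumsum(positive)[cut]
    fps = np.cumsum(~positive)[cut]
    tpr = np.r_[0.0, tps / max(int(positive.sum()), 1)]
    fpr = np.r_[0.0, fps / max(int((~positive).sum()), 1)]
    return fpr, tpr


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def roc_ovr(
    scores: np.ndarray, truth: Sequence[str], class_order: Sequence[str]
) -> ROCResult:
    """One-vs-rest ROC per class from the continuous score columns.

    The trapezoidal AUC on the tie-grouped curve equals the tie-adjusted
    Mann-Whitney concordance probability.  Classes absent from ``truth`` (or
    filling it entirely) have no defined AUC and are omitted from the map.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(list(truth), dtype=object)
    if scores.ndim != 2 or scores.shape != (truth.size, len(class_order)):
        raise ValueError("scores must be (m, K) aligned with truth and class_order")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    fpr_map: dict[str, np.ndarray] = {}
    tpr_map: dict[str, np.ndarray] = {}
    auc_map: dict[str, float] = {}
    for k, cls in enumerate(class_order):
        positive = truth == cls
        if positive.sum() == 0 or positive.all():
            continue
        fpr, tpr = _binary_roc(scores[:, k], positive)
        fpr_map[cls], tpr_map[cls] = fpr, tpr
        auc_map[cls] = auc_trapezoid(fpr, tpr)
    return ROCResult(
        class_order=tuple(class_order), fpr=fpr_map, tpr=tpr_map, auc=auc_map
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CVReport:
    k: int
    fold_metrics: list[ClassMetrics]
    mean_accuracy: float
    sd_accuracy: float
    fold_assignment: np.ndarray  # fold index per spectrum


def _stratified_folds(
    dataset: SpectralDataset, k: int, mode: str, rng: np.random.Generator
) -> np.ndarray:
    """Fold index per row; strata are classes, units spectra or whole cells."""
    folds = np.full(dataset.n_spectra, -1, dtype=int)
    for cls in dataset.class_order:
        rows = np.flatnonzero(dataset.labels == cls)
        if rows.size == 0:
            continue
        if mode == "spectrum":
            if rows.size < k:
                raise ValueError(f"class {cls!r} has fewer than k={k} spectra")
            perm = rng.permutation(rows)
            folds[perm] = np.arange(perm.size) % k
        else:
            cells = np.array(sorted({str(c) for c in dataset.cell_ids[rows]}))
            if cells.size < k:
                raise ValueError(f"class {cls!r} has fewer than k={k} cells")
            perm = rng.permutation(cells)
            fold_of = {cell: i % k for i, cell in enumerate(perm)}
            folds[rows] = [fold_of[str(c)] for c in dataset.cell_ids[rows]]
    return folds


def cross_validate(
    dataset: SpectralDataset,
    k: int = 5,
    n_components: int = 2,
    mode: str = "spectrum",
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV of the PLS-DA classifier on a preprocessed dataset."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(dataset, k, mode, rng)
    fold_metrics: list[ClassMetrics] = []
    for fold in range(k):
        test_mask = folds == fold
        train = dataset.subset(~test_mask)
        test = dataset.subset(test_mask)
        model = fit_plsda_dataset(train, n_components=n_components)
        predicted = classify(model, test.matrix)
        cm = confusion_matrix(list(test.labels), list(predicted), dataset.class_order)
        fold_metrics.append(classification_metrics(cm))
    accs = np.array([m.accuracy for m in fold_metrics])
    return CVReport(
        k=k,
        fold_metrics=fold_metrics,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if k > 1 else 0.0,
        fold_assignment=folds,
    )


# ---------------------------------------------------------------------------
# Band statistics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BandStats:
    center: float
    half_width: float
    class_order: tuple[str, ...]
    mean: dict[str, float]
    sd: dict[str, float]
    n: dict[str, int]
    #: (class_a, class_b) -> (t statistic, two-sided p); degenerate pairs -> None
    t_tests: dict[tuple[str, str], Optional[tuple[float, float]]]
    values: dict[str, np.ndarray]  # per-spectrum band means per class


def band_statistics(
    dataset: SpectralDataset,
    center: float,
    half_width: float = 2.0,
    equal_var: bool = True,
    bonferroni: bool = False,
) -> BandStats:
    """Per-class statistics of the band-mean intensity, with pairwise t-tests.

    The default is Student's pooled-variance two-sample t-test; ``equal_var
    = False`` switches to Welch.  ``bonferroni`` multiplies each two-sided
    p-value by the number of pairwise comparisons (capped at 1); it is off
    by default, matching the uncorrected convention of exploratory band
    comparisons.  A pair where both groups have zero variance has no defined
    test and is reported as ``None`` rather than p = 0.
    """
    mask = dataset.grid.band_mask(center - half_width, center + half_width)
    if not mask.any():
        raise ValueError(f"band {center} +/- {half_width} cm^-1 outside grid")
    band = dataset.matrix[:, mask].mean(axis=1)
    values: dict[str, np.ndarray] = {}
    for cls in dataset.class_order:
        vals = band[dataset.labels == cls]
        if vals.size < 2:
            raise ValueError(f"class {cls!r} needs n >= 2 spectra")
        values[cls] = vals
    mean = {c: float(v.mean()) for c, v in values.items()}
    sd = {c: float(v.std(ddof=1)) for c, v in values.items()}
    n = {c: int(v.size) for c, v in values.items()}
    t_tests: dict[tuple[str, str], Optional[tuple[float, float]]] = {}
    order = dataset.class_order
    n_pairs = len(order) * (len(order) - 1) // 2
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            a, b = values[order[i]], values[order[j]]
            if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
                t_tests[(order[i], order[j])] = None
                continue
            t, pval = stats.ttest_ind(a, b, equal_var=equal_var)
            if bonferroni:
                pval = min(1.0, float(pval) * n_pairs)
            t_tests[(order[i], order[j])] = (float(t), float(pval))
    return BandStats(
        center=center,
        half_width=half_width,
        class_order=order,
        mean=mean,
        sd=sd,
        n=n,
        t_tests=t_tests,
        values=values,
    )
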