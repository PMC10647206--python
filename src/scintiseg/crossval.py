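"""Patient-wise nested cross-validation, fold aggregation and ROC analysis.

The study design: patients (not images) are partitioned into 10 buckets
of 4 or 5, so all four views of a patient stay together and no patient
leaks between training and testing.  Each outer fold holds one bucket
out for testing; within the remaining nine, nine inner fits are run
(each holding a different bucket out as validation), the candidate with
the best validation score is selected, and only that model sees the
test bucket.  Reported tables give per-fold values with mean ± sample
standard deviation across the ten folds.

Image-level classification is derived from segmentation: an image is
truly "inflamed" when its reference labels contain at least one low- or
high-inflammation pixel, and a prediction is called inflamed when its
combined inflamed mask holds at least t pixels.  Sweeping t from 0 to
one past the pixel count of an image traces the ROC; t = 0 forces
(TPR, FPR) = (1, 1) and the far end reaches (0, 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import labels as _labels
from .labels import SEGMENTED_CLASSES, clip_combine, combine_inflammation
from .metrics import ConfusionMatrix, MetricRecord, modified_dice, modified_iou
from .phantom import Cohort
from .threshold import GridSpec, ThresholdParams, _grid_search, predict

logger = logging.getLogger(__name__)

_CLASS_CODES = {"normal": _labels.NORMAL, "low": _labels.LOW, "high": _labels.HIGH}


# --------------------------------------------------------------------------
# folds
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSpec:
    """Assignment of each patient to exactly one bucket."""

    buckets: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for bucket in self.buckets:
            if not bucket:
                raise ValueError("empty bucket in fold specification")
            dup = seen.intersection(bucket)
            if dup:
                raise ValueError(f"patients in multiple buckets: {sorted(dup)}")
            seen.update(bucket)

    @property
    def n_buckets(self) -> int:
        return len(self.buckets)

    @property
    def patient_ids(self) -> list[str]:
        return [p for b in self.buckets for p in b]

    def split(self, fold_id: int) -> tuple[tuple[str, ...], list[tuple[str, ...]]]:
        """(test bucket, train/validation buckets) of one outer fold."""
        test = self.buckets[fold_id]
        trainval = [b for i, b in enumerate(self.buckets) if i != fold_id]
        return test, trainval


def make_folds(
    patient_ids: Sequence[str], n_buckets: int = 10, seed: int = 0
) -> FoldSpec:
    """Seeded shuffle + round-robin assignment of patients to buckets."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    if len(ids) < n_buckets:
        raise ValueError(
            f"need at least {n_buckets} patients, got {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    buckets: list[list[str]] = [[] for _ in range(n_buckets)]
    for i, pid in enumerate(order):
        buckets[i % n_buckets].append(pid)
    return FoldSpec(buckets=tuple(tuple(b) for b in buckets))


def assert_no_patient_leakage(
    test_patients: Sequence[str], train_patients: Sequence[str]
) -> None:
    """Harness-level guard: a test patient must never be trained on."""
    shared = set(test_patients) & set(train_patients)
    if shared:
        raise AssertionError(
            f"patient leakage between train and test: {sorted(shared)}"
        )


# --------------------------------------------------------------------------
# fold evaluation
# --------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold_id: int
    image_ids: list[str]
    class_dice: dict[str, float]
    class_iou: dict[str, float]
    all_dice: float
    all_iou: float
    combined_dice: float
    combined_iou: float
    records: list[MetricRecord]
    confusion: ConfusionMatrix
    inflamed_pixel_counts: dict[str, int]
    truth_inflamed: dict[str, bool]
    params: ThresholdParams | None = None
    inner_validation_scores: list[float] | None = None
    selected_inner: int | None = None


def evaluate_fold(
    predictions: Mapping[str, object],
    truths: Mapping[str, np.ndarray],
    fold_id: int,
) -> FoldResult:
    """Score one fold's predictions against fused reference maps.

    ``predictions`` maps image id -> RawLabelSet-like per-class masks
    (any segmenter source, including externally produced mask files);
    ``truths`` maps image id -> fused reference map.  Per-class scores
    use the raw independent masks against the class's binary reference;
    the combined inflamed score clips the summed low/high predictions;
    the confusion matrix uses severity-fused exclusive maps.
    """
    missing = [i for i in truths if i not in predictions]
    if missing:
        raise ValueError(f"missing predictions for test images: {sorted(missing)}")
    image_ids = list(truths)
    records: list[MetricRecord] = []
    per_class = {c: {"dice": [], "iou": []} for c in SEGMENTED_CLASSES}
    combined_d: list[float] = []
    combined_i: list[float] = []
    conf = ConfusionMatrix()
    counts: dict[str, int] = {}
    truth_flags: dict[str, bool] = {}

    for image_id in image_ids:
        raw_pred = predictions[image_id]
        fused_truth = np.asarray(truths[image_id])
        for cls in SEGMENTED_CLASSES:
            pred_mask = raw_pred.mask(cls)
            truth_mask = fused_truth == _CLASS_CODES[cls]
            d = modified_dice(pred_mask, truth_mask)
            j = modified_iou(pred_mask, truth_mask)
            per_class[cls]["dice"].append(d)
            per_class[cls]["iou"].append(j)
            records.append(MetricRecord(image_id, cls, d, j))
        pred_inflamed = clip_combine(raw_pred.mask("low"), raw_pred.mask("high"))
        truth_inflamed = combine_inflammation(fused_truth)
        combined_d.append(modified_dice(pred_inflamed, truth_inflamed))
        combined_i.append(modified_iou(pred_inflamed, truth_inflamed))
        records.append(
            MetricRecord(image_id, "inflamed", combined_d[-1], combined_i[-1])
        )
        conf.add(fused_truth, _labels.fuse_labels(raw_pred))
        counts[image_id] = int(pred_inflamed.sum())
        truth_flags[image_id] = bool(truth_inflamed.any())

    class_dice = {c: float(np.mean(per_class[c]["dice"])) for c in SEGMENTED_CLASSES}
    class_iou = {c: float(np.mean(per_class[c]["iou"])) for c in SEGMENTED_CLASSES}
    return FoldResult(
        fold_id=fold_id,
        image_ids=image_ids,
        class_dice=class_dice,
        class_iou=class_iou,
        all_dice=float(np.mean(list(class_dice.values()))),
        all_iou=float(np.mean(list(class_iou.values()))),
        combined_dice=float(np.mean(combined_d)),
        combined_iou=float(np.mean(combined_i)),
        records=records,
        confusion=conf,
        inflamed_pixel_counts=counts,
        truth_inflamed=truth_flags,
    )


def aggregate_folds(per_fold: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Mean ± standard deviation across fold rows, one column per score.

    Sample standard deviation (ddof=1) by default — the convention that
    reproduces the published thresholding-table ± values most closely.
    """
    df = pd.DataFrame(per_fold)
    if len(df) < 2:
        raise ValueError("need at least two folds for a standard deviation")
    return pd.DataFrame(
        {"mean": df.mean(axis=0), "std": df.std(axis=0, ddof=ddof)}
    ).T


def format_mean_std(agg: pd.DataFrame, decimals: int = 2) -> pd.Series:
    """Render an aggregate row like the published tables: '0.92 ± 0.01'."""
    return pd.Series(
        {
            col: f"{agg.loc['mean', col]:.{decimals}f} ± {agg.loc['std', col]:.{decimals}f}"
            for col in agg.columns
        }
    )


# --------------------------------------------------------------------------
# ROC from segmentation pixel counts
# --------------------------------------------------------------------------

@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def at_threshold(self, t: int) -> tuple[float, float]:
        idx = int(np.searchsorted(self.thresholds, t))
        if idx >= self.thresholds.size or self.thresholds[idx] != t:
            raise ValueError(f"threshold {t} outside the swept range")
        return float(self.tpr[idx]), float(self.fpr[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_from_counts(
    counts: Sequence[int], truth_labels: Sequence[bool], n_pixels: int
) -> RocCurve:
    """ROC over pixel-count thresholds t in {0, 1, ..., N, N+1}.

    An image is called inflamed when its predicted inflamed-pixel count
    is >= t.  t = 0 gives (TPR, FPR) = (1, 1); t = N+1 guarantees the
    (0, 0) endpoint even if some prediction is fully inflamed.  AUC by
    the trapezoid rule over (FPR, TPR).
    """
    counts = np.asarray(counts, dtype=np.int64)
    truth = np.asarray(truth_labels, dtype=bool)
    if counts.shape != truth.shape:
        raise ValueError("counts and truth labels must align")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0:
        raise ValueError("no truly inflamed image: TPR undefined")
    if n_neg == 0:
        raise ValueError("no inflammation-free image: FPR undefined")
    thresholds = np.arange(0, n_pixels + 2, dtype=np.int64)
    pos_sorted = np.sort(counts[truth])
    neg_sorted = np.sort(counts[~truth])
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="left")
    tpr = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def roc_from_predictions(
    pred_inflamed: Sequence[np.ndarray], truth_fused: Sequence[np.ndarray]
) -> RocCurve:
    """ROC from per-image predicted inflamed masks and fused references."""
    preds = [np.asarray(p) for p in pred_inflamed]
    truths = [np.asarray(t) for t in truth_fused]
    if len(preds) != len(truths):
        raise ValueError("predictions and truths must align")
    sizes = {p.size for p in preds} | {t.size for t in truths}
    if len(sizes) != 1:
        raise ValueError("all images must share one size for the pixel sweep")
    counts = [int(p.sum()) for p in preds]
    flags = [bool(combine_inflammation(t).any()) for t in truths]
    return roc_from_counts(counts, flags, n_pixels=sizes.pop())


def operating_point(
    pred_inflamed: Sequence[np.ndarray],
    truth_fused: Sequence[np.ndarray],
    t: int = 1,
) -> tuple[float, float]:
    """(sensitivity, specificity) at pixel-count threshold ``t``."""
    roc = roc_from_predictions(pred_inflamed, truth_fused)
    tpr, fpr = roc.at_threshold(t)
    return tpr, 1.0 - fpr


# --------------------------------------------------------------------------
# nested cross-validation of the thresholding model
# --------------------------------------------------------------------------

@dataclass
class EvalReport:
    folds: list[FoldResult]
    per_class_table: pd.DataFrame
    combined_table: pd.DataFrame
    per_class_summary: pd.DataFrame
    combined_summary: pd.DataFrame
    confusion: ConfusionMatrix
    roc: RocCurve | None
    operating_sensitivity: float | None
    operating_specificity: float | None
    records: pd.DataFrame = field(default_factory=pd.DataFrame)


def _tables_from_folds(folds: list[FoldResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    per_class = pd.DataFrame(
        [
            {
                "fold": f.fold_id,
                "normal": f.class_dice["normal"],
                "low": f.class_dice["low"],
                "high": f.class_dice["high"],
                "all": f.all_dice,
            }
            for f in folds
        ]
    ).set_index("fold")
    combined = pd.DataFrame(
        [{"fold": f.fold_id, "inflamed": f.combined_dice} for f in folds]
    ).set_index("fold")
    return per_class, combined


def build_report(folds: list[FoldResult]) -> EvalReport:
    """Assemble fold results into tables, pooled confusion and pooled ROC."""
    per_class, combined = _tables_from_folds(folds)
    conf = ConfusionMatrix()
    counts: list[int] = []
    flags: list[bool] = []
    for f in folds:
        conf.merge(f.confusion)
        for image_id in f.image_ids:
            counts.append(f.inflamed_pixel_counts[image_id])
            flags.append(f.truth_inflamed[image_id])
    n_pixels = None
    roc = None
    sens = spec = None
    try:
        # pixel count per image comes from any fold's test images; the
        # harness enforces a uniform image size upstream
        n_pixels = _uniform_n_pixels(folds)
        roc = roc_from_counts(counts, flags, n_pixels)
        tpr, fpr = roc.at_threshold(1)
        sens, spec = tpr, 1.0 - fpr
    except ValueError as exc:
        logger.warning("ROC unavailable: %s", exc)
    records = pd.DataFrame(
        [
            {
                "fold": f.fold_id,
                "image_id": r.image_id,
                "class": r.class_name,
                "modified_dice": r.modified_dice,
                "modified_iou": r.modified_iou,
            }
            for f in folds
            for r in f.records
        ]
    )
    return EvalReport(
        folds=folds,
        per_class_table=per_class,
        combined_table=combined,
        per_class_summary=aggregate_folds(per_class),
        combined_summary=aggregate_folds(combined),
        confusion=conf,
        roc=roc,
        operating_sensitivity=sens,
        operating_specificity=spec,
        records=records,
    )


def _uniform_n_pixels(folds: list[FoldResult]) -> int:
    sizes = {f.confusion.counts.sum() // max(len(f.image_ids), 1) for f in folds}
    if len(sizes) != 1:
        raise ValueError("folds disagree on the per-image pixel count")
    return int(sizes.pop())


def nested_cv_threshold(
    cohort: Cohort, folds: FoldSpec, grid: GridSpec | None = None
) -> EvalReport:
    """Nested patient-wise cross-validation of the thresholding model.

    Per outer fold: nine inner fits (each train/validation bucket held
    out once as validation), selection of the inner candidate with the
    highest mean modified Dice (unweighted over the three classes) on
    its validation bucket — ties break to the lowest inner index — and
    evaluation of only the selected model on the outer test bucket.
    """
    grid = grid or GridSpec()
    by_id = {r.image_id: r for r in cohort.records}
    ids = list(by_id)
    idx_of = {image_id: i for i, image_id in enumerate(ids)}
    pixel_arrays = [np.asarray(by_id[i].scan.pixels, dtype=float) for i in ids]
    truth_maps = [by_id[i].fused for i in ids]

    fold_results: list[FoldResult] = []
    for fold_id in range(folds.n_buckets):
        test_patients, trainval_buckets = folds.split(fold_id)
        trainval_patients = [p for b in trainval_buckets for p in b]
        assert_no_patient_leakage(test_patients, trainval_patients)

        bucket_image_idx = [
            [idx_of[r.image_id] for r in cohort.records_of(bucket)]
            for bucket in trainval_buckets
        ]
        if any(len(b) == 0 for b in bucket_image_idx):
            raise ValueError(f"outer fold {fold_id}: empty train/validation bucket")
        subsets = [
            [i for j, b in enumerate(bucket_image_idx) if j != held for i in b]
            for held in range(len(trainval_buckets))
        ]
        candidates = _grid_search(pixel_arrays, truth_maps, grid, subsets)

        val_scores: list[float] = []
        for held, params in enumerate(candidates):
            scores = []
            for i in bucket_image_idx[held]:
                raw_pred, _ = predict(params, pixel_arrays[i])
                per_class = [
                    modified_dice(
                        raw_pred.mask(c), truth_maps[i] == _CLASS_CODES[c]
                    )
                    for c in SEGMENTED_CLASSES
                ]
                scores.append(float(np.mean(per_class)))
            val_scores.append(float(np.mean(scores)))
        selected = int(np.argmax(val_scores))  # ties -> lowest inner index
        params = candidates[selected]
        logger.info(
            "outer fold %d: selected inner fold %d (validation Dice %.4f)",
            fold_id,
            selected,
            val_scores[selected],
        )

        test_records = cohort.records_of(test_patients)
        if not test_records:
            raise ValueError(f"outer fold {fold_id}: empty test bucket")
        predictions = {}
        truths = {}
        for rec in test_records:
            raw_pred, _ = predict(params, rec.scan.pixels)
            predictions[rec.image_id] = raw_pred
            truths[rec.image_id] = rec.fused
        result = evaluate_fold(predictions, truths, fold_id)
        result.params = params
        result.inner_validation_scores = val_scores
        result.selected_inner = selected
        fold_results.append(result)

    return build_report(fold_results)


def evaluate_external(
    cohort: Cohort,
    folds: FoldSpec,
    predictions: Mapping[str, object],
) -> EvalReport:
    """Fold-wise evaluation of externally produced per-class masks.

    The comparison path for segmenters trained outside this package
    (e.g. a CNN): predictions enter as RawLabelSet-like objects keyed by
    image id and are scored with the same fold structure and metrics.
    """
    fold_results = []
    for fold_id in range(folds.n_buckets):
        test_patients, _ = folds.split(fold_id)
        test_records = cohort.records_of(test_patients)
        preds = {}
        truths = {}
        for rec in test_records:
            if rec.image_id not in predictions:
                raise ValueError(f"missing external prediction for {rec.image_id}")
            preds[rec.image_id] = predictions[rec.image_id]
            truths[rec.image_id] = rec.fused
        fold_results.append(evaluate_fold(preds, truths, fold_id))
    return build_report(fold_results)
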