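"""Folds, nested selection, aggregation arithmetic and the pixel-count ROC."""

import numpy as np
import pandas as pd
import pytest

from scintiseg.crossval import (
    FoldSpec,
    aggregate_folds,
    assert_no_patient_leakage,
    build_report,
    evaluate_fold,
    make_folds,
    nested_cv_threshold,
    operating_point,
    roc_from_counts,
    roc_from_predictions,
)
from scintiseg.labels import HIGH, LOW, NORMAL, RawLabelSet
from scintiseg.metrics import modified_dice
from scintiseg.phantom import Cohort, CohortRecord, ScanImage
from scintiseg.threshold import GridSpec, fit, predict
from tests.conftest import make_band_images, raw_from_fused


# --------------------------------------------------------------------------
# folds
# --------------------------------------------------------------------------

def test_48_patients_make_buckets_of_4_or_5():
    ids = [f"P{i:03d}" for i in range(48)]
    folds = make_folds(ids, n_buckets=10, seed=0)
    sizes = sorted(len(b) for b in folds.buckets)
    assert sizes == [4, 4, 5, 5, 5, 5, 5, 5, 5, 5]
    assert sorted(folds.patient_ids) == sorted(ids)


def test_each_patient_in_exactly_one_bucket():
    ids = [f"P{i}" for i in range(23)]
    folds = make_folds(ids, n_buckets=10, seed=3)
    seen = [p for b in folds.buckets for p in b]
    assert sorted(seen) == sorted(ids)


def test_singleton_buckets_and_too_few_patients():
    folds = make_folds([f"P{i}" for i in range(10)], n_buckets=10, seed=1)
    assert all(len(b) == 1 for b in folds.buckets)
    with pytest.raises(ValueError):
        make_folds(["a", "b"], n_buckets=10)


def test_fold_spec_rejects_duplicates_and_empties():
    with pytest.raises(ValueError):
        FoldSpec(buckets=(("a",), ("a",)))
    with pytest.raises(ValueError):
        FoldSpec(buckets=(("a",), ()))


def test_leakage_guard():
    with pytest.raises(AssertionError):
        assert_no_patient_leakage(["a", "b"], ["b", "c"])
    assert_no_patient_leakage(["a"], ["b"])  # disjoint is fine


# --------------------------------------------------------------------------
# fold evaluation and aggregation
# --------------------------------------------------------------------------

def _mask_with(n_ones, size=16):
    m = np.zeros(size, dtype=np.uint8)
    m[:n_ones] = 1
    return m.reshape(4, -1)


def test_evaluate_fold_perfect_predictions_score_one():
    from scintiseg.labels import one_hot

    fused = np.array([[NORMAL, LOW], [HIGH, 0]], dtype=np.uint8)
    preds = {"img": one_hot(fused)}
    result = evaluate_fold(preds, {"img": fused}, fold_id=0)
    assert all(v == 1.0 for v in result.class_dice.values())
    assert result.all_dice == 1.0 and result.combined_dice == 1.0


def test_evaluate_fold_means_per_image_scores():
    # two test images engineered to Dice 0.4 and 0.6 on the low class
    truth_a = np.zeros((4, 4), dtype=np.uint8)
    truth_a.flat[:5] = LOW
    pred_a = np.zeros((4, 4), dtype=np.uint8)
    pred_a.flat[3:8] = 1  # |X|=5, |Y|=5, overlap 2 -> 0.4
    truth_b = np.zeros((4, 4), dtype=np.uint8)
    truth_b.flat[:5] = LOW
    pred_b = np.zeros((4, 4), dtype=np.uint8)
    pred_b.flat[2:7] = 1  # overlap 3 -> 0.6
    zeros = np.zeros((4, 4), dtype=np.uint8)
    preds = {
        "a": RawLabelSet(normal=zeros, low=pred_a, high=zeros),
        "b": RawLabelSet(normal=zeros, low=pred_b, high=zeros),
    }
    result = evaluate_fold(preds, {"a": truth_a, "b": truth_b}, fold_id=0)
    assert result.class_dice["low"] == pytest.approx(0.5)


def test_evaluate_fold_requires_all_predictions():
    fused = np.zeros((2, 2), dtype=np.uint8)
    with pytest.raises(ValueError, match="missing"):
        evaluate_fold({}, {"img": fused}, fold_id=0)


def test_all_column_is_unweighted_class_mean():
    # the published fold-1 row: (0.93 + 0.2 + 0.28) / 3 rounds to 0.47
    row = pd.Series({"normal": 0.93, "low": 0.2, "high": 0.28})
    assert round(float(row.mean()), 2) == 0.47


def test_aggregate_reproduces_published_column_means():
    normal_col = [0.93, 0.93, 0.91, 0.91, 0.92, 0.92, 0.91, 0.92, 0.93, 0.90]
    agg = aggregate_folds(pd.DataFrame({"normal": normal_col}))
    assert round(float(agg.loc["mean", "normal"]), 2) == 0.92
    assert round(float(agg.loc["std", "normal"]), 2) == 0.01
    combined_col = [0.34, 0.5, 0.39, 0.2, 0.26, 0.68, 0.72, 0.28, 0.21, 0.42]
    agg2 = aggregate_folds(pd.DataFrame({"inflamed": combined_col}))
    assert round(float(agg2.loc["mean", "inflamed"]), 2) == 0.4
    assert round(float(agg2.loc["std", "inflamed"]), 2) == 0.18


def test_aggregate_identical_folds_zero_std_and_min_folds():
    agg = aggregate_folds(pd.DataFrame({"x": [0.5] * 10}))
    assert agg.loc["std", "x"] == 0.0
    with pytest.raises(ValueError):
        aggregate_folds(pd.DataFrame({"x": [0.5]}))


def test_combined_score_bounded_below_when_one_class_empty():
    # truth and prediction both lack high pixels: combined Dice must not
    # fall below the worse of the two per-class scores
    rng = np.random.default_rng(8)
    for _ in range(20):
        truth = np.zeros((6, 6), dtype=np.uint8)
        truth.flat[rng.choice(36, 6, replace=False)] = LOW
        pred_low = (rng.random((6, 6)) < 0.3).astype(np.uint8)
        zeros = np.zeros((6, 6), dtype=np.uint8)
        preds = {"i": RawLabelSet(normal=zeros, low=pred_low, high=zeros)}
        res = evaluate_fold(preds, {"i": truth}, fold_id=0)
        assert res.combined_dice >= min(res.class_dice["low"], res.class_dice["high"]) - 1e-12


# --------------------------------------------------------------------------
# ROC
# --------------------------------------------------------------------------

def _toy_roc_setup():
    counts = [0, 3, 10, 0, 1, 7]
    truth = [False, True, True, False, False, True]
    return counts, truth, 16


def test_roc_endpoints():
    counts, truth, n_pix = _toy_roc_setup()
    roc = roc_from_counts(counts, truth, n_pix)
    tpr0, fpr0 = roc.at_threshold(0)
    assert (tpr0, fpr0) == (1.0, 1.0)
    tpr_end, fpr_end = roc.at_threshold(n_pix + 1)
    assert (tpr_end, fpr_end) == (0.0, 0.0)
    # no prediction is fully inflamed, so the endpoint already holds at N
    tpr_n, fpr_n = roc.at_threshold(n_pix)
    assert (tpr_n, fpr_n) == (0.0, 0.0)


def test_roc_matches_exhaustive_threshold_oracle():
    counts, truth, n_pix = _toy_roc_setup()
    roc = roc_from_counts(counts, truth, n_pix)
    counts = np.array(counts)
    truth = np.array(truth)
    for t in range(n_pix + 2):
        called = counts >= t
        tpr = (called & truth).sum() / truth.sum()
        fpr = (called & ~truth).sum() / (~truth).sum()
        got_tpr, got_fpr = roc.at_threshold(t)
        assert got_tpr == pytest.approx(tpr)
        assert got_fpr == pytest.approx(fpr)
    assert np.all(np.diff(roc.tpr) <= 1e-12) and np.all(np.diff(roc.fpr) <= 1e-12)
    assert 0.0 <= roc.auc <= 1.0


def test_roc_auc_matches_sklearn():
    sk = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(4)
    counts = rng.integers(0, 30, size=40)
    truth = rng.random(40) < 0.5
    roc = roc_from_counts(counts, truth, n_pixels=64)
    assert roc.auc == pytest.approx(sk.roc_auc_score(truth, counts))


def test_roc_from_masks_perfect_predictions_auc_one():
    rng = np.random.default_rng(9)
    truths = []
    preds = []
    for i in range(6):
        fused = np.zeros((5, 5), dtype=np.uint8)
        if i % 2:
            fused.flat[rng.choice(25, 3, replace=False)] = HIGH
        truths.append(fused)
        preds.append(((fused == LOW) | (fused == HIGH)).astype(np.uint8))
    roc = roc_from_predictions(preds, truths)
    assert roc.auc == 1.0


def test_roc_requires_both_strata():
    with pytest.raises(ValueError, match="free"):
        roc_from_counts([1, 2], [True, True], 4)
    with pytest.raises(ValueError, match="inflamed"):
        roc_from_counts([1, 2], [False, False], 4)


def test_operating_point_examples():
    # 3 positives all detected; 4 negatives, one carrying a false pixel
    counts = [5, 2, 9, 0, 0, 0, 1]
    truth = [True, True, True, False, False, False, False]
    preds = []
    truths = []
    for c, t in zip(counts, truth):
        p = np.zeros((4, 4), dtype=np.uint8)
        p.flat[:c] = 1
        f = np.zeros((4, 4), dtype=np.uint8)
        if t:
            f.flat[0] = HIGH
        preds.append(p)
        truths.append(f)
    sens, spec = operating_point(preds, truths, t=1)
    assert (sens, spec) == (1.0, 0.75)


def test_operating_point_always_alarming_predictor():
    preds = [np.ones((3, 3), dtype=np.uint8) for _ in range(4)]
    truths = [np.zeros((3, 3), dtype=np.uint8) for _ in range(4)]
    truths[0] = np.full((3, 3), HIGH, dtype=np.uint8)
    sens, spec = operating_point(preds, truths, t=1)
    assert (sens, spec) == (1.0, 0.0)


# --------------------------------------------------------------------------
# nested cross-validation
# --------------------------------------------------------------------------

def _toy_cohort(n_patients=6, views=2, seed=21):
    """Small band-structured cohort with patient-correlated noise."""
    rng = np.random.default_rng(seed)
    scans, truths = make_band_images(n_images=n_patients * views, side=12, seed=seed)
    records = []
    patients = []
    k = 0
    from scintiseg.phantom import PatientState

    for p in range(n_patients):
        pid = f"P{p}"
        patients.append(PatientState(patient_id=pid, has_low=True, has_high=True))
        for v in range(views):
            img = scans[k] + rng.normal(0, 1.0, scans[k].shape).round()
            img = np.clip(img, 0, 100)
            records.append(
                CohortRecord(
                    image_id=f"{pid}_v{v}",
                    patient_id=pid,
                    view="palmar",
                    scan=ScanImage(pixels=img, patient_id=pid, view="palmar"),
                    raw=raw_from_fused(truths[k]),
                    fused=truths[k],
                )
            )
            k += 1
    return Cohort(config=None, patients=patients, records=records)


def test_nested_cv_selection_matches_independent_oracle():
    cohort = _toy_cohort()
    folds = make_folds(cohort.patient_ids, n_buckets=3, seed=0)
    grid = GridSpec(sigma_values=(0.1, 1.0), threshold_levels=(0, 10, 20, 40, 60, 80))
    report = nested_cv_threshold(cohort, folds, grid)
    assert len(report.folds) == 3

    for fold_res in report.folds:
        fold_id = fold_res.fold_id
        _, trainval_buckets = folds.split(fold_id)
        # oracle: fit each inner candidate independently, score on its
        # validation bucket, pick the best (ties -> lowest index)
        oracle_scores = []
        oracle_params = []
        for held, val_bucket in enumerate(trainval_buckets):
            train_recs = [
                r
                for b in trainval_buckets
                if b != val_bucket
                for r in cohort.records_of(b)
            ]
            params = fit([(r.scan.pixels, r.fused) for r in train_recs], grid)
            oracle_params.append(params)
            val_recs = cohort.records_of(val_bucket)
            img_scores = []
            for r in val_recs:
                raw, _ = predict(params, r.scan.pixels)
                img_scores.append(
                    np.mean(
                        [
                            modified_dice(raw.mask(c), r.fused == code)
                            for code, c in ((NORMAL, "normal"), (LOW, "low"), (HIGH, "high"))
                        ]
                    )
                )
            oracle_scores.append(float(np.mean(img_scores)))
        assert fold_res.inner_validation_scores == pytest.approx(oracle_scores)
        expected_choice = int(np.argmax(oracle_scores))
        assert fold_res.selected_inner == expected_choice
        assert fold_res.params == oracle_params[expected_choice]


def test_nested_cv_single_candidate_grid_is_trivial():
    cohort = _toy_cohort(n_patients=3, views=1)
    folds = make_folds(cohort.patient_ids, n_buckets=3, seed=0)
    grid = GridSpec(sigma_values=(1.0,), threshold_levels=(10,))
    report = nested_cv_threshold(cohort, folds, grid)
    for fold_res in report.folds:
        for cls in ("normal", "low", "high"):
            assert fold_res.params.for_class(cls) == (1.0, 10.0, 10.0)


def test_nested_cv_handles_inflammation_free_bucket():
    # one bucket holds only lesion-free patients; the empty-empty metric
    # rule lets the pipeline complete with well-defined scores
    cohort = _toy_cohort(n_patients=3, views=1)
    clean = np.zeros((12, 12), dtype=np.uint8)
    clean_img = np.zeros((12, 12))
    for rec in cohort.records_of(["P2"]):
        rec.fused = clean
        rec.raw = raw_from_fused(clean)
        rec.scan = ScanImage(pixels=clean_img, patient_id=rec.patient_id, view="palmar")
    folds = make_folds(cohort.patient_ids, n_buckets=3, seed=0)
    grid = GridSpec(sigma_values=(0.1,), threshold_levels=(0, 20, 40, 80))
    report = nested_cv_threshold(cohort, folds, grid)
    assert all(np.isfinite(f.all_dice) for f in report.folds)


def test_every_image_tested_exactly_once():
    cohort = _toy_cohort()
    folds = make_folds(cohort.patient_ids, n_buckets=3, seed=5)
    grid = GridSpec(sigma_values=(0.1,), threshold_levels=(0, 40, 80))
    report = nested_cv_threshold(cohort, folds, grid)
    tested = [i for f in report.folds for i in f.image_ids]
    assert sorted(tested) == sorted(r.image_id for r in cohort.records)


def test_report_summary_shapes():
    cohort = _toy_cohort()
    folds = make_folds(cohort.patient_ids, n_buckets=3, seed=5)
    grid = GridSpec(sigma_values=(0.1,), threshold_levels=(0, 10, 40, 80))
    report = nested_cv_threshold(cohort, folds, grid)
    assert list(report.per_class_table.columns) == ["normal", "low", "high", "all"]
    assert set(report.per_class_summary.index) == {"mean", "std"}
    assert report.confusion.counts.sum() == sum(
        r.fused.size for r in cohort.records
    )
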