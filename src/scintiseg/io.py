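"""On-disk formats, run configuration and the end-to-end pipeline.

Canonical dialect: scans as 16-bit grayscale PNG, raw label masks as
8-bit binary PNG (0/255), fused class maps as 8-bit indexed PNG with a
fixed four-entry palette, and a cohort manifest CSV tying image ids to
patients, views and file paths.  NIfTI mirroring of the same arrays is
available for interoperability with medical-imaging toolchains.  All
round-trips are lossless on the integer display scale.

``run_pipeline`` ties generation -> label fusion -> fold construction ->
nested cross-validation (or external-mask evaluation) -> report files,
embedding a provenance block (config hash, seed, package version) so
every artifact is re-derivable from the run configuration alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .crossval import (
    EvalReport,
    evaluate_external,
    format_mean_std,
    make_folds,
    nested_cv_threshold,
)
from .labels import FUSED_PALETTE, RawLabelSet, fuse_labels
from .phantom import (
    Cohort,
    CohortRecord,
    PhantomConfig,
    ScanImage,
    cohort_statistics,
    generate_cohort,
)
from .threshold import GridSpec

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class DataError(ValueError):
    """Unreadable, malformed or out-of-range data file."""


# --------------------------------------------------------------------------
# image round-trips
# --------------------------------------------------------------------------

def write_scan(scan, path) -> None:
    """Write a display-scaled scan as 16-bit grayscale PNG."""
    pixels = scan.pixels if hasattr(scan, "pixels") else np.asarray(scan)
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise DataError(f"scan must be 2D, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise DataError("scan values outside the 16-bit range")
    Image.fromarray(arr.astype(np.uint16)).save(path, format="PNG")


def read_scan(path, display_max: int | None = None) -> np.ndarray:
    """Read a 16-bit grayscale PNG scan; rejects multi-channel content."""
    try:
        img = Image.open(path)
    except (FileNotFoundError, OSError) as exc:
        raise DataError(f"cannot read scan {path}: {exc}") from exc
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise DataError(
            f"{path}: expected a single grayscale channel, got {arr.ndim}D "
            f"content with {arr.shape[-1]} channels"
        )
    if arr.min() < 0:
        raise DataError(f"{path}: negative pixel values")
    if display_max is not None and arr.max() > display_max:
        raise DataError(
            f"{path}: pixel values exceed display maximum {display_max}"
        )
    return arr.astype(np.uint16)


def write_mask(mask, path) -> None:
    """Write a binary mask as 8-bit PNG (0 / 255)."""
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise DataError("mask must be binary")
    Image.fromarray((arr * 255).astype(np.uint8)).save(path, format="PNG")


def read_mask(path) -> np.ndarray:
    try:
        arr = np.asarray(Image.open(path))
    except (FileNotFoundError, OSError) as exc:
        raise DataError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim != 2:
        raise DataError(f"{path}: mask must be single-channel")
    return (arr > 0).astype(np.uint8)


def write_fused(fused, path) -> None:
    """Write a fused class map as indexed PNG with the fixed 4-entry palette."""
    arr = np.asarray(fused)
    if arr.min() < 0 or arr.max() > 3:
        raise DataError("fused map classes must lie in 0..3")
    img = Image.fromarray(arr.astype(np.uint8), mode="P")
    palette = [v for rgb in FUSED_PALETTE for v in rgb]
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(path, format="PNG")


def read_fused(path) -> np.ndarray:
    try:
        img = Image.open(path)
    except (FileNotFoundError, OSError) as exc:
        raise DataError(f"cannot read fused map {path}: {exc}") from exc
    if img.mode != "P":
        raise DataError(f"{path}: fused maps must be indexed PNG")
    arr = np.asarray(img).astype(np.uint8)
    if arr.max() > 3:
        raise DataError(f"{path}: class index above 3")
    return arr


# --------------------------------------------------------------------------
# cohort on disk
# --------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write scans, raw masks, fused maps and the manifest; returns manifest path."""
    out = Path(out_dir)
    for sub in ("scans", "labels", "fused"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.records:
        scan_path = out / "scans" / f"{rec.image_id}.png"
        write_scan(rec.scan, scan_path)
        label_paths = {}
        for cls in ("normal", "low", "high"):
            p = out / "labels" / f"{rec.image_id}_{cls}.png"
            write_mask(rec.raw.mask(cls), p)
            label_paths[cls] = p
        fused_path = out / "fused" / f"{rec.image_id}.png"
        write_fused(rec.fused, fused_path)
        rows.append(
            {
                "image_id": rec.image_id,
                "patient_id": rec.patient_id,
                "view": rec.view,
                "scan_path": scan_path.relative_to(out).as_posix(),
                "normal_path": label_paths["normal"].relative_to(out).as_posix(),
                "low_path": label_paths["low"].relative_to(out).as_posix(),
                "high_path": label_paths["high"].relative_to(out).as_posix(),
                "fused_path": fused_path.relative_to(out).as_posix(),
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    config_doc = {"phantom": cohort.config.to_dict()} if cohort.config else {}
    (out / "cohort_config.json").write_text(json.dumps(config_doc, indent=2))
    return manifest


def load_cohort(manifest_path) -> Cohort:
    """Reconstruct a cohort from a manifest CSV and its referenced files."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DataError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    if df["image_id"].duplicated().any():
        raise DataError("duplicate image ids in manifest")
    records = []
    patients: dict[str, None] = {}
    for row in df.itertuples(index=False):
        scan = ScanImage(
            pixels=read_scan(base / row.scan_path),
            patient_id=row.patient_id,
            view=row.view,
        )
        raw = RawLabelSet(
            normal=read_mask(base / row.normal_path),
            low=read_mask(base / row.low_path),
            high=read_mask(base / row.high_path),
        )
        fused = read_fused(base / row.fused_path)
        records.append(
            CohortRecord(
                image_id=row.image_id,
                patient_id=row.patient_id,
                view=row.view,
                scan=scan,
                raw=raw,
                fused=fused,
            )
        )
        patients.setdefault(row.patient_id)
    from .phantom import PatientState  # local import to avoid cycle noise

    patient_states = [
        PatientState(patient_id=p, has_low=False, has_high=False) for p in patients
    ]
    return Cohort(config=None, patients=patient_states, records=records)


def export_nifti(cohort: Cohort, out_dir) -> None:
    """Mirror scans and fused maps as NIfTI volumes (optional adapter)."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in cohort.records:
        affine = np.eye(4)
        nib.save(
            nib.Nifti1Image(rec.scan.pixels.astype(np.int16), affine),
            out / f"{rec.image_id}_scan.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(rec.fused.astype(np.uint8), affine),
            out / f"{rec.image_id}_fused.nii.gz",
        )


def load_external_predictions(pred_dir, image_ids) -> dict[str, RawLabelSet]:
    """Read per-class mask files ``{image_id}_{class}.png`` for each image."""
    pred_dir = Path(pred_dir)
    if not pred_dir.is_dir():
        raise DataError(f"external mask directory not found: {pred_dir}")
    out = {}
    for image_id in image_ids:
        masks = {}
        for cls in ("normal", "low", "high"):
            p = pred_dir / f"{image_id}_{cls}.png"
            if not p.exists():
                raise DataError(f"missing external mask: {p}")
            masks[cls] = read_mask(p)
        out[image_id] = RawLabelSet(**masks)
    return out


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Fully seeded description of one pipeline run."""

    phantom: PhantomConfig
    n_folds: int = 10
    fold_seed: int = 0
    model: str = "threshold"
    sigma_values: tuple[float, ...] | None = None
    threshold_levels: tuple[int, ...] | None = None
    external_masks: str | None = None
    out_dir: str = "report"
    log_level: str = "INFO"
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.model not in ("threshold", "external"):
            raise ConfigError(f"unknown model {self.model!r}")
        if self.model == "external" and not self.external_masks:
            raise ConfigError("external model requires external_masks directory")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be at least 2")

    def grid(self) -> GridSpec:
        kwargs = {}
        if self.sigma_values is not None:
            kwargs["sigma_values"] = tuple(self.sigma_values)
        if self.threshold_levels is not None:
            kwargs["threshold_levels"] = tuple(self.threshold_levels)
        return GridSpec(**kwargs)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["phantom"] = self.phantom.to_dict()
        return doc

    def config_hash(self) -> str:
        # hash the scientific configuration only: where the report is
        # written or how verbosely it logs does not change the result
        doc = self.to_dict()
        for key in ("out_dir", "log_level", "make_figures"):
            doc.pop(key, None)
        canon = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        phantom_doc = doc.pop("phantom", None)
        if phantom_doc is None:
            raise ConfigError("configuration must contain a 'phantom' section")
        if "seed" not in phantom_doc:
            raise ConfigError("phantom configuration must carry a seed")
        try:
            phantom = PhantomConfig(**phantom_doc)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid phantom configuration: {exc}") from exc
        for key in ("sigma_values", "threshold_levels"):
            if doc.get(key) is not None:
                doc[key] = tuple(doc[key])
        try:
            return cls(phantom=phantom, **doc)
        except TypeError as exc:
            raise ConfigError(f"invalid run configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"configuration file not found: {path}")
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        return cls.from_dict(doc)


# --------------------------------------------------------------------------
# report writing
# --------------------------------------------------------------------------

def write_report(report: EvalReport, out_dir, provenance: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_class = report.per_class_table.round(4)
    per_class.to_csv(out / "per_class_dice.csv")
    report.combined_table.round(4).to_csv(out / "combined_dice.csv")
    report.per_class_summary.round(4).to_csv(out / "per_class_summary.csv")
    report.combined_summary.round(4).to_csv(out / "combined_summary.csv")
    report.records.to_csv(out / "per_image_metrics.csv", index=False)
    report.confusion.to_dataframe(normalize=True).round(6).to_csv(
        out / "confusion_normalized.csv"
    )
    report.confusion.to_dataframe(normalize=False).to_csv(out / "confusion_counts.csv")
    if report.roc is not None:
        report.roc.to_dataframe().to_csv(out / "roc_points.csv", index=False)
    summary = {
        "per_class_mean_std": {
            col: format_mean_std(report.per_class_summary)[col]
            for col in report.per_class_summary.columns
        },
        "combined_mean_std": {
            col: format_mean_std(report.combined_summary)[col]
            for col in report.combined_summary.columns
        },
        "auc": report.roc.auc if report.roc else None,
        "sensitivity_at_1px": report.operating_sensitivity,
        "specificity_at_1px": report.operating_specificity,
        "provenance": provenance,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def write_figures(report: EvalReport, out_dir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(6, 4))
    data = [report.per_class_table[c] for c in ("normal", "low", "high", "all")]
    ax.boxplot(data, tick_labels=["normal", "low", "high", "all"])
    ax.set_ylabel("modified Dice")
    ax.set_title("Per-fold modified Dice by class")
    fig.savefig(out / "dice_boxplot.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4.5))
    norm = report.confusion.normalized()
    im = ax.imshow(norm, vmin=0, vmax=1, cmap="Blues")
    names = ["background", "normal", "low", "high"]
    ax.set_xticks(range(4), names, rotation=45)
    ax.set_yticks(range(4), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(4):
        for j in range(4):
            ax.text(j, i, f"{norm[i, j]:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im)
    fig.savefig(out / "confusion.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    if report.roc is not None:
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(report.roc.fpr, report.roc.tpr, label=f"AUC = {report.roc.auc:.2f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        fig.savefig(out / "roc.png", dpi=120, bbox_inches="tight")
        plt.close(fig)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> EvalReport:
    """Generate -> fuse -> fold -> evaluate -> report, fully seeded."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    file_handler = logging.FileHandler(out / "pipeline.log")
    logging.getLogger().addHandler(file_handler)
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.phantom.seed,
        "fold_seed": config.fold_seed,
        "package_version": __version__,
    }
    try:
        logger.info("stage=config hash=%s seed=%d", provenance["config_hash"],
                    config.phantom.seed)
        if config.model == "external":
            # fail before any computation if the mask source is absent
            if not Path(config.external_masks).is_dir():
                raise DataError(
                    f"external mask directory not found: {config.external_masks}"
                )
        logger.info("stage=generate n_patients=%d", config.phantom.n_patients)
        cohort = generate_cohort(config.phantom)
        write_cohort(cohort, out / "cohort")
        stats = cohort_statistics(cohort)
        (out / "cohort_statistics.json").write_text(
            json.dumps(stats.to_dict(), indent=2)
        )
        logger.info("stage=folds n_folds=%d", config.n_folds)
        folds = make_folds(cohort.patient_ids, config.n_folds, config.fold_seed)
        if config.model == "threshold":
            logger.info("stage=nested_cv")
            report = nested_cv_threshold(cohort, folds, config.grid())
        else:
            logger.info("stage=external_eval dir=%s", config.external_masks)
            preds = load_external_predictions(
                config.external_masks, [r.image_id for r in cohort.records]
            )
            report = evaluate_external(cohort, folds, preds)
        logger.info("stage=report out=%s", out)
        write_report(report, out, provenance)
        if config.make_figures:
            write_figures(report, out / "figures")
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        return report
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        logging.getLogger().removeHandler(file_handler)
        file_handler.close()
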