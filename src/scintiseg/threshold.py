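"""Learnable Gaussian-smooth band-threshold segmenter.

The baseline model for segmenting normal, low- and high-inflammation
tissue in display-scaled planar scintigraphy images.  Each class is
learned independently as a band threshold on a Gaussian-smoothed copy of
the image: a pixel belongs to class c when

    lower_c <= G(sigma_c) * image <= upper_c        (inclusive bounds)

giving nine trainable parameters in total (sigma, lower, upper per
class).  The smoothing kernel is a normalized, truncated 2D Gaussian
whose square support side follows the kernel-size rule

    k = round(max(3*sigma, 1));  k + 1 if k is even, else k

with round-half-away-from-zero.  Fitting is exhaustive grid search,
per class, maximizing the mean modified Dice between the band mask and
the class's binary ground truth over the training images.  Because each
class is thresholded independently, a pixel can carry several raw class
predictions; severity fusion resolves them for confusion-matrix use.

Grid search is exact but organized for reuse: for a given sigma each
image is smoothed once and a full (lower, upper) Dice table is built
from sorted pixel values, so scoring all threshold pairs costs a couple
of searchsorted calls per image instead of one pass per pair.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import convolve1d

from . import labels
from .labels import SEGMENTED_CLASSES, RawLabelSet

__all__ = [
    "ThresholdParams",
    "GridSpec",
    "kernel_size",
    "gaussian_smooth",
    "band_threshold",
    "predict",
    "fit",
]

_CLASS_CODES = {"normal": labels.NORMAL, "low": labels.LOW, "high": labels.HIGH}


def kernel_size(sigma: float) -> int:
    """Odd square-support side for a Gaussian of width ``sigma`` pixels.

    round(max(3*sigma, 1)) with half-away-from-zero rounding, bumped to
    the next integer when even so the kernel has a center pixel.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    k = int(math.floor(max(3.0 * sigma, 1.0) + 0.5))
    return k + 1 if k % 2 == 0 else k


def _gauss_kernel_1d(sigma: float) -> np.ndarray:
    half = (kernel_size(sigma) - 1) // 2
    x = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def gaussian_smooth(image, sigma: float) -> np.ndarray:
    """Smooth with the truncated, normalized Gaussian of ``kernel_size``.

    The 2D kernel is the outer product of the truncated 1D kernel with
    itself (normalizing the product equals normalizing each factor), so
    the convolution is applied separably.  Borders use reflect padding.
    """
    image = np.asarray(image, dtype=np.float64)
    w = _gauss_kernel_1d(sigma)
    if w.size == 1:
        return image.copy()
    out = convolve1d(image, w, axis=0, mode="reflect")
    return convolve1d(out, w, axis=1, mode="reflect")


def band_threshold(smoothed, lower: float, upper: float) -> np.ndarray:
    """Binary mask of pixels with ``lower <= value <= upper`` (inclusive)."""
    if lower > upper:
        raise ValueError(f"lower ({lower}) must not exceed upper ({upper})")
    smoothed = np.asarray(smoothed)
    return ((smoothed >= lower) & (smoothed <= upper)).astype(np.uint8)


@dataclass(frozen=True)
class ThresholdParams:
    """The segmenter's nine learned values: (sigma, lower, upper) per class."""

    sigma_normal: float
    lower_normal: float
    upper_normal: float
    sigma_low: float
    lower_low: float
    upper_low: float
    sigma_high: float
    lower_high: float
    upper_high: float

    def __post_init__(self) -> None:
        for name in SEGMENTED_CLASSES:
            sigma, lower, upper = self.for_class(name)
            if sigma <= 0:
                raise ValueError(f"sigma_{name} must be positive")
            if lower > upper:
                raise ValueError(f"lower_{name} exceeds upper_{name}")

    def for_class(self, class_name: str) -> tuple[float, float, float]:
        return (
            getattr(self, f"sigma_{class_name}"),
            getattr(self, f"lower_{class_name}"),
            getattr(self, f"upper_{class_name}"),
        )

    def to_dict(self) -> dict[str, float]:
        return {
            f"{kind}_{cls}": float(getattr(self, f"{kind}_{cls}"))
            for cls in SEGMENTED_CLASSES
            for kind in ("sigma", "lower", "upper")
        }

    @property
    def n_parameters(self) -> int:
        return len(self.to_dict())

    def to_json(self, path, **provenance) -> None:
        doc = {"parameters": self.to_dict()}
        if provenance:
            doc["provenance"] = provenance
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ThresholdParams":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**doc["parameters"])


@dataclass(frozen=True)
class GridSpec:
    """Search space of the grid fit.

    ``sigma_values`` defaults to 0.1 .. 4.0 in steps of 0.1.
    ``threshold_levels`` defaults to the integers from 0 up to the
    maximum pixel value of the training set, resolved at fit time when
    left as None.
    """

    sigma_values: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 41))
    threshold_levels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        sig = np.asarray(self.sigma_values, dtype=float)
        if sig.size == 0 or np.any(np.diff(sig) <= 0) or np.any(sig <= 0):
            raise ValueError("sigma_values must be non-empty, positive, increasing")
        if self.threshold_levels is not None:
            lev = np.asarray(self.threshold_levels)
            if lev.size == 0 or np.any(np.diff(lev) <= 0):
                raise ValueError("threshold_levels must be non-empty and increasing")

    def resolve_levels(self, images: Sequence[np.ndarray]) -> np.ndarray:
        if self.threshold_levels is not None:
            return np.asarray(self.threshold_levels, dtype=float)
        top = int(max(int(np.max(img)) for img in images))
        return np.arange(0, top + 1, dtype=float)


def predict(params: ThresholdParams, scan) -> tuple[RawLabelSet, np.ndarray]:
    """Segment one scan: raw independent per-class masks plus fused map.

    Smoothing is shared between classes with equal sigma.  The fused map
    resolves multi-class pixels by severity for confusion-matrix use.
    """
    pixels = scan.pixels if hasattr(scan, "pixels") else np.asarray(scan)
    smoothed_cache: dict[float, np.ndarray] = {}
    masks = {}
    for cls in SEGMENTED_CLASSES:
        sigma, lower, upper = params.for_class(cls)
        if sigma not in smoothed_cache:
            smoothed_cache[sigma] = gaussian_smooth(pixels, sigma)
        masks[cls] = band_threshold(smoothed_cache[sigma], lower, upper)
    raw = RawLabelSet(**masks)
    return raw, labels.fuse_labels(raw)


def _dice_table(sorted_all, sorted_truth, n_truth, levels) -> np.ndarray:
    """Modified-Dice table over all (lower, upper) level pairs of one image.

    Row index = lower level, column index = upper level.  Entries with
    upper < lower are filled later by the caller's validity mask.  Uses
    |X| and |X∩Y| from cumulative counts of the sorted smoothed values
    (inclusive band: value >= lower and value <= upper).
    """
    le_all = np.searchsorted(sorted_all, levels, side="right")
    lt_all = np.searchsorted(sorted_all, levels, side="left")
    x = le_all[None, :] - lt_all[:, None]
    if n_truth:
        le_t = np.searchsorted(sorted_truth, levels, side="right")
        lt_t = np.searchsorted(sorted_truth, levels, side="left")
        inter = le_t[None, :] - lt_t[:, None]
    else:
        inter = np.zeros_like(x)
    denom = x + n_truth
    with np.errstate(invalid="ignore", divide="ignore"):
        dice = np.where(denom > 0, 2.0 * inter / denom, 1.0)
    return dice


def _grid_search(
    pixel_arrays: Sequence[np.ndarray],
    truth_maps: Sequence[np.ndarray],
    grid: GridSpec,
    subsets: Sequence[Sequence[int]],
) -> list[ThresholdParams]:
    """Exhaustive per-class band search for several training subsets at once.

    ``subsets`` are index lists into ``pixel_arrays``; one ThresholdParams
    is returned per subset (nested cross-validation scores nine heavily
    overlapping subsets, so per-image Dice tables are shared).  Smoothing
    for a given sigma is computed once per image and reused across all
    threshold pairs and subsets.  Tie-break: smallest sigma, then
    smallest lower, then smallest upper (scores compared with strict >,
    scanning sigmas in ascending order and tables row-major).
    """
    if not subsets or any(len(s) == 0 for s in subsets):
        raise ValueError("every training subset must be non-empty")
    levels = grid.resolve_levels([pixel_arrays[i] for s in subsets for i in s])
    n_lev = levels.size
    # rows index the lower level, columns the upper; upper < lower is invalid
    invalid = ~np.triu(np.ones((n_lev, n_lev), dtype=bool))
    needed = sorted({i for s in subsets for i in s})
    membership = [
        [si for si, s in enumerate(subsets) if i in set(s)] for i in needed
    ]

    best_score = np.full((len(subsets), 3), -np.inf)
    best_triple: list[list[tuple[float, float, float] | None]] = [
        [None] * 3 for _ in subsets
    ]
    class_codes = [_CLASS_CODES[c] for c in SEGMENTED_CLASSES]

    for sigma in grid.sigma_values:
        sums = np.zeros((len(subsets), 3, n_lev, n_lev))
        for pos, img_idx in enumerate(needed):
            smoothed = gaussian_smooth(pixel_arrays[img_idx], sigma)
            sorted_all = np.sort(smoothed, axis=None)
            for ci, code in enumerate(class_codes):
                truth = truth_maps[img_idx] == code
                n_truth = int(np.count_nonzero(truth))
                sorted_truth = np.sort(smoothed[truth]) if n_truth else None
                table = _dice_table(sorted_all, sorted_truth, n_truth, levels)
                for si in membership[pos]:
                    sums[si, ci] += table
        for si, subset in enumerate(subsets):
            mean = sums[si] / len(subset)
            mean[:, invalid] = -np.inf
            for ci in range(3):
                top = mean[ci].max()
                if top > best_score[si, ci]:
                    lo_i, up_i = np.argwhere(mean[ci] == top)[0]
                    best_score[si, ci] = top
                    best_triple[si][ci] = (
                        float(sigma),
                        float(levels[lo_i]),
                        float(levels[up_i]),
                    )

    out = []
    for triples in best_triple:
        kwargs = {}
        for cls, (sigma, lower, upper) in zip(SEGMENTED_CLASSES, triples):
            kwargs[f"sigma_{cls}"] = sigma
            kwargs[f"lower_{cls}"] = lower
            kwargs[f"upper_{cls}"] = upper
        out.append(ThresholdParams(**kwargs))
    return out


def fit(train_set: Iterable[tuple], grid: GridSpec | None = None) -> ThresholdParams:
    """Grid-search fit on (scan, fused truth) pairs.

    For each class independently, every (sigma, lower <= upper) triple is
    scored by the mean modified Dice between its band mask and the
    class's binary ground truth over the training images; the maximizer
    is returned (deterministic tie-break, see ``_grid_search``).
    """
    grid = grid or GridSpec()
    pixels, truths = [], []
    for scan, fused in train_set:
        pixels.append(
            np.asarray(scan.pixels if hasattr(scan, "pixels") else scan, dtype=float)
        )
        truths.append(np.asarray(fused))
    if not pixels:
        raise ValueError("training set is empty")
    return _grid_search(pixels, truths, grid, [list(range(len(pixels)))])[0]
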