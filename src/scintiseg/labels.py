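"""Label fusion and inflammation-class combination.

Clinician-style annotations of planar hand scans mark three possibly
overlapping regions per image: normal tissue, low inflammation and high
inflammation.  Downstream analysis needs a mutually exclusive per-pixel
class map, obtained by severity fusion: wherever masks overlap the most
severe class wins (high > low > normal > background).  The numeric class
codes are chosen in severity order so that fusion is a per-pixel maximum.

A second, separate operation collapses low and high inflammation into a
single "inflamed" class, either from an already-exclusive fused map
(where pixel-wise addition is guaranteed binary) or from independent
per-class predictions (where the sum is clipped to {0, 1}, since a band
thresholder may mark one pixel as several classes at once).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BACKGROUND = 0
NORMAL = 1
LOW = 2
HIGH = 3

CLASS_NAMES = ("background", "normal", "low", "high")
#: classes with their own learned segmentation (everything but background)
SEGMENTED_CLASSES = ("normal", "low", "high")
#: fixed RGB palette for indexed-PNG storage of fused maps
FUSED_PALETTE = (
    (0, 0, 0),        # background
    (130, 130, 130),  # normal
    (255, 200, 0),    # low inflammation
    (220, 30, 30),    # high inflammation
)


def _as_binary(mask, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} mask must contain only 0/1 values")
    return arr.astype(np.uint8)


@dataclass
class RawLabelSet:
    """Three independently stored binary masks; overlap is permitted."""

    normal: np.ndarray
    low: np.ndarray
    high: np.ndarray

    def __post_init__(self) -> None:
        self.normal = _as_binary(self.normal, "normal")
        self.low = _as_binary(self.low, "low")
        self.high = _as_binary(self.high, "high")
        if not (self.normal.shape == self.low.shape == self.high.shape):
            raise ValueError("raw label masks must share one shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.normal.shape

    def mask(self, class_name: str) -> np.ndarray:
        return getattr(self, class_name)


def fuse_labels(raw: RawLabelSet) -> np.ndarray:
    """Collapse overlapping masks to one class per pixel by severity.

    Returns a uint8 map over {0=background, 1=normal, 2=low, 3=high}.
    A pixel in no mask is background.
    """
    fused = np.zeros(raw.shape, dtype=np.uint8)
    fused[raw.normal > 0] = NORMAL
    fused[raw.low > 0] = LOW
    fused[raw.high > 0] = HIGH
    return fused


def class_mask(fused: np.ndarray, class_code: int) -> np.ndarray:
    """Binary mask of one class of a fused map."""
    return (np.asarray(fused) == class_code).astype(np.uint8)


def one_hot(fused: np.ndarray) -> RawLabelSet:
    """Expand a fused map back to three (now disjoint) binary masks."""
    return RawLabelSet(
        normal=class_mask(fused, NORMAL),
        low=class_mask(fused, LOW),
        high=class_mask(fused, HIGH),
    )


def combine_inflammation(fused: np.ndarray) -> np.ndarray:
    """Single inflamed class from an exclusive map: 1 where low or high.

    Mutual exclusivity of the fused map guarantees that adding the low
    and high indicator masks never exceeds one.
    """
    fused = np.asarray(fused)
    return ((fused == LOW) | (fused == HIGH)).astype(np.uint8)


def clip_combine(low: np.ndarray, high: np.ndarray) -> np.ndarray:
    """Single inflamed class from independent per-class predictions.

    Pixel-wise sum clipped to {0, 1}: a pixel predicted as both low and
    high counts once.
    """
    low = np.asarray(low)
    high = np.asarray(high)
    if low.shape != high.shape:
        raise ValueError("low/high masks must share one shape")
    return np.clip(low.astype(np.int64) + high.astype(np.int64), 0, 1).astype(np.uint8)
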