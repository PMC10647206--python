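"""Shared fixtures: tiny deterministic images and phantom configs."""

from __future__ import annotations

import numpy as np
import pytest

from scintiseg import PhantomConfig
from scintiseg.labels import RawLabelSet, fuse_labels


def make_band_images(n_images: int = 3, side: int = 16, seed: int = 7):
    """Noise-free piecewise-constant scans whose classes are exact bands.

    Pixel values: background 0, normal 10, low 40, high 80, so with an
    identity smoothing any exact band recovers each class perfectly.
    Returns (scans, fused_truths).
    """
    rng = np.random.default_rng(seed)
    scans, truths = [], []
    for _ in range(n_images):
        img = np.zeros((side, side), dtype=float)
        fused = np.zeros((side, side), dtype=np.uint8)
        # random rectangular normal region with embedded lesions
        r0, c0 = rng.integers(0, side // 3, size=2)
        r1, c1 = rng.integers(2 * side // 3, side, size=2)
        img[r0:r1, c0:c1] = 10
        fused[r0:r1, c0:c1] = 1
        lr, lc = rng.integers(r0, max(r0 + 1, r1 - 2)), rng.integers(c0, max(c0 + 1, c1 - 2))
        img[lr : lr + 2, lc : lc + 2] = 40
        fused[lr : lr + 2, lc : lc + 2] = 2
        hr, hc = rng.integers(r0, max(r0 + 1, r1 - 1)), rng.integers(c0, max(c0 + 1, c1 - 1))
        img[hr, hc] = 80
        fused[hr, hc] = 3
        scans.append(img)
        truths.append(fused)
    return scans, truths


@pytest.fixture
def band_training_set():
    scans, truths = make_band_images()
    return list(zip(scans, truths))


@pytest.fixture
def small_phantom_config():
    """A fast, reduced-scale phantom configuration for smoke-level tests."""
    return PhantomConfig(
        seed=42,
        image_size=128,
        n_patients=4,
        views_per_patient=2,
        lesion_size_mean_low=30.0,
        lesion_size_std_low=20.0,
        lesion_size_mean_high=60.0,
        lesion_size_std_high=40.0,
        lesion_size_max=400,
    )


def raw_from_fused(fused: np.ndarray) -> RawLabelSet:
    return RawLabelSet(
        normal=(fused >= 1).astype(np.uint8),
        low=(fused == 2).astype(np.uint8),
        high=(fused == 3).astype(np.uint8),
    )
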