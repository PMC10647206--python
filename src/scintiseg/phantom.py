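"""Synthetic planar hand-scan cohort generator.

Clinical ⁹⁹ᵐTc-maraciclatide hand scans cannot be redistributed, so the
pipeline is exercised on a seeded phantom cohort that emulates the
printed summary statistics of the study dataset: 48 patients x 4 views
of 256x256 display-scaled count maps in which roughly 0.42% of pixels
are highly inflamed and 0.25% carry low inflammation, 56/192 images have
no low-inflammation pixels, 87/192 no high, 45/192 neither, and the mean
8-connected lesion component holds about 62.81 px (low) / 121.25 px
(high).

Each phantom is a hand silhouette (palm ellipse, knuckle bar, five
finger/thumb capsules and a wrist block, pose varied by view), with the
raw "normal" mask equal to the full silhouette and inflammation lesions
placed at joint-like loci so the raw masks overlap non-exclusively, as
clinician annotations do.  Latent intensity is piecewise constant per
class, blurred by a Gaussian point-spread function, Poisson count noise
is applied, and counts are linearly rescaled and rounded to the 0..100
display scale the clinician annotated on.

Calibration model (all defaults derive from the printed statistics):

* each patient is healthy, low-only, high-only, or both, with
  probabilities chosen so the expected empty-image counts are exactly
  56, 87 and 45 of 192;
* each image of an affected patient draws a Poisson number of lesions
  per class (zero allowed — that, together with the patient states,
  carries the empty-image calibration);
* lesion pixel counts are lognormal with the printed mean ± std; a
  lesion is rasterized as the first-n-pixels-by-distance prefix of a
  disk, so its component size equals the sampled count exactly, and a
  one-pixel separation between lesions keeps 8-connected components
  from merging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from . import labels as _labels
from .labels import RawLabelSet, fuse_labels

logger = logging.getLogger(__name__)

VIEWS = ("palmar", "dorsal", "oblique1", "oblique2")
#: base rotation (degrees) of the hand pose for each acquisition view
_VIEW_ANGLES = {"palmar": 0.0, "dorsal": 4.0, "oblique1": -10.0, "oblique2": 10.0}


@dataclass
class PhantomConfig:
    """All generator parameters; defaults are the calibrated study conditions.

    Intensities are mean count levels in arbitrary gamma-camera count
    units; ``count_scale_max`` is the fixed count level mapped to
    ``display_max`` on export (fixed display scaling across the cohort).
    Patient-state probabilities and per-image lesion-count rates solve
    the empty-image and pixel-mass calibration exactly in expectation;
    lesion sizes are lognormal with the printed mean ± std per class.
    """

    seed: int
    image_size: int = 256
    n_patients: int = 48
    views_per_patient: int = 4
    display_max: int = 100

    # latent mean count intensities, arbitrary count units
    lambda_background: float = 1.0
    lambda_normal: float = 150.0
    lambda_low: float = 400.0
    lambda_high: float = 800.0
    count_scale_max: float = 1000.0
    psf_sigma: float = 1.2

    # patient-level inflammation state
    p_patient_has_low: float = 0.72866
    p_patient_has_high: float = 0.55626
    p_patient_has_both: float = 0.51227

    # per-image lesion counts for affected patients: zero-inflated Poisson
    # (an affected patient's view shows no lesion with probability
    # p_image_free_*, else a Poisson(lesion_rate_*) number of lesions)
    lesion_rate_low: float = 3.579929
    lesion_rate_high: float = 4.080946
    p_image_free_low: float = 0.000714
    p_image_free_high: float = 0.011073

    # lesion pixel-count distribution (lognormal, per class)
    lesion_size_mean_low: float = 62.81
    lesion_size_std_low: float = 82.55
    lesion_size_mean_high: float = 121.25
    lesion_size_std_high: float = 130.65
    lesion_size_min: int = 1
    lesion_size_max: int = 3000

    max_placement_attempts: int = 60

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (
            self.lambda_background
            < self.lambda_normal
            < self.lambda_low
            < self.lambda_high
        ):
            raise ValueError(
                "intensities must satisfy background < normal < low < high"
            )
        for name in (
            "p_patient_has_low",
            "p_patient_has_high",
            "p_patient_has_both",
            "p_image_free_low",
            "p_image_free_high",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_patient_has_both > min(
            self.p_patient_has_low, self.p_patient_has_high
        ):
            raise ValueError("p_patient_has_both exceeds a marginal probability")
        if (
            self.p_patient_has_low
            + self.p_patient_has_high
            - self.p_patient_has_both
        ) > 1.0 + 1e-12:
            raise ValueError("patient-state probabilities exceed 1")
        for name in ("image_size", "n_patients", "views_per_patient", "display_max"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.views_per_patient > len(VIEWS):
            raise ValueError(f"at most {len(VIEWS)} views are defined")
        if self.lesion_size_min < 1 or self.lesion_size_max < self.lesion_size_min:
            raise ValueError("invalid lesion size bounds")
        if self.psf_sigma <= 0 or self.count_scale_max <= 0:
            raise ValueError("psf_sigma and count_scale_max must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PatientState:
    """Per-patient inflammation flags, sampled once and shared across views."""

    patient_id: str
    has_low: bool
    has_high: bool


@dataclass
class ScanImage:
    """One planar view's display-scaled count grid with identity."""

    pixels: np.ndarray
    patient_id: str
    view: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("scan must be a square 2D grid")
        if self.pixels.min() < 0:
            raise ValueError("scan pixels must be non-negative")


@dataclass
class CohortRecord:
    image_id: str
    patient_id: str
    view: str
    scan: ScanImage
    raw: RawLabelSet
    fused: np.ndarray


@dataclass
class Cohort:
    config: PhantomConfig
    patients: list[PatientState]
    records: list[CohortRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CohortRecord]:
        return iter(self.records)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def records_of(self, patient_ids: Sequence[str]) -> list[CohortRecord]:
        wanted = set(patient_ids)
        return [r for r in self.records if r.patient_id in wanted]


# --------------------------------------------------------------------------
# hand geometry
# --------------------------------------------------------------------------

# canonical layout on a 256-px grid, (row, col) coordinates
_PALM = {"center": (148.0, 128.0), "ay": 40.0, "ax": 38.0}
_KNUCKLE_BAR = {"p0": (115.0, 98.0), "p1": (115.0, 158.0), "r": 13.0}
_WRIST = {"p0": (192.0, 128.0), "p1": (225.0, 128.0), "r": 24.0}
_FINGERS = [  # base, tip, radius
    {"p0": (112.0, 96.0), "p1": (48.0, 88.0), "r": 9.0},    # index
    {"p0": (110.0, 120.0), "p1": (36.0, 116.0), "r": 9.5},  # middle
    {"p0": (110.0, 142.0), "p1": (42.0, 146.0), "r": 9.0},  # ring
    {"p0": (113.0, 162.0), "p1": (64.0, 172.0), "r": 8.0},  # pinky
    {"p0": (150.0, 88.0), "p1": (118.0, 48.0), "r": 10.0},  # thumb
]
#: joint-like lesion loci: fractions along each finger base->tip
_FINGER_JOINT_FRACTIONS = (0.2, 0.5, 0.8)
_PALM_LOCI = [(135.0, 110.0), (140.0, 145.0), (160.0, 128.0)]
_WRIST_LOCI = [(200.0, 112.0), (200.0, 144.0), (215.0, 128.0)]


def _rotate(points: np.ndarray, angle_deg: float, center: float) -> np.ndarray:
    theta = np.deg2rad(angle_deg)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    return (points - center) @ rot.T + center


def _capsule_mask(grid_yx, p0, p1, radius) -> np.ndarray:
    yy, xx = grid_yx
    v = np.asarray(p1) - np.asarray(p0)
    denom = float(v @ v)
    dy = yy - p0[0]
    dx = xx - p0[1]
    t = np.clip((dy * v[0] + dx * v[1]) / denom, 0.0, 1.0) if denom > 0 else 0.0
    ry = dy - t * v[0]
    rx = dx - t * v[1]
    return ry * ry + rx * rx <= radius * radius


def _ellipse_mask(grid_yx, center, ay, ax, angle_deg) -> np.ndarray:
    yy, xx = grid_yx
    theta = np.deg2rad(angle_deg)
    dy = yy - center[0]
    dx = xx - center[1]
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    return (u / ay) ** 2 + (v / ax) ** 2 <= 1.0


def _hand_geometry(
    config: PhantomConfig, view: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Silhouette mask and joint-like lesion loci for one posed view."""
    n = config.image_size
    s = n / 256.0
    angle = _VIEW_ANGLES.get(view, 0.0) + rng.uniform(-3.0, 3.0)
    shift = rng.uniform(-3.0, 3.0, size=2) * s
    center = 128.0 * s

    def pose(pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float)) * s
        return _rotate(pts, angle, center) + shift

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    grid = (yy, xx)

    palm_c = pose(_PALM["center"])[0]
    mask = _ellipse_mask(grid, palm_c, _PALM["ay"] * s, _PALM["ax"] * s, angle)
    for cap in (_KNUCKLE_BAR, _WRIST, *_FINGERS):
        p0 = pose(cap["p0"])[0]
        p1 = pose(cap["p1"])[0]
        mask |= _capsule_mask(grid, p0, p1, cap["r"] * s)

    loci = []
    for f in _FINGERS:
        base = np.asarray(f["p0"])
        tip = np.asarray(f["p1"])
        for frac in _FINGER_JOINT_FRACTIONS:
            loci.append(base + frac * (tip - base))
    loci.extend(_PALM_LOCI)
    loci.extend(_WRIST_LOCI)
    return mask, pose(np.asarray(loci))


# --------------------------------------------------------------------------
# lesion blobs
# --------------------------------------------------------------------------

_MAX_BLOB_RADIUS = 64


def _blob_offsets() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disk pixel offsets sorted by (distance², dy, dx); cached."""
    r = _MAX_BLOB_RADIUS
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    dy = dy.ravel()
    dx = dx.ravel()
    d2 = dy * dy + dx * dx
    order = np.lexsort((dx, dy, d2))
    return dy[order], dx[order], np.sqrt(d2[order].astype(float))


_BLOB_DY, _BLOB_DX, _BLOB_R = _blob_offsets()


def _blob(n_pixels: int) -> tuple[np.ndarray, np.ndarray, float]:
    """First ``n_pixels`` of the distance-ordered disk: an 8-connected
    blob of exactly ``n_pixels`` pixels, plus its outer radius."""
    if n_pixels > _BLOB_DY.size:
        raise ValueError(f"lesion of {n_pixels} px exceeds the blob template")
    return _BLOB_DY[:n_pixels], _BLOB_DX[:n_pixels], float(_BLOB_R[n_pixels - 1])


def _place_lesions(
    silhouette: np.ndarray,
    loci: np.ndarray,
    lesion_specs: list[tuple[str, int]],
    config: PhantomConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Place requested (class, size) lesions inside the silhouette.

    Largest lesions are placed first to limit size-dependent skips; a
    lesion is accepted when it fits fully inside the silhouette (checked
    via the Euclidean distance transform at its center) and its 1-px
    dilation is disjoint from every previously placed lesion, so same-
    class components never merge.  Placement failure after bounded
    retries skips the lesion with a logged warning.
    """
    n = config.image_size
    edt = ndimage.distance_transform_edt(silhouette)
    masks = {
        "low": np.zeros((n, n), dtype=np.uint8),
        "high": np.zeros((n, n), dtype=np.uint8),
    }
    occupied = np.zeros((n, n), dtype=bool)
    loci_int = np.rint(loci).astype(int)

    for cls, size in sorted(lesion_specs, key=lambda t: -t[1]):
        dy, dx, r_out = _blob(size)
        placed = False
        for _ in range(config.max_placement_attempts):
            locus = loci_int[rng.integers(len(loci_int))]
            cy = int(locus[0] + rng.integers(-5, 6))
            cx = int(locus[1] + rng.integers(-5, 6))
            if not (0 <= cy < n and 0 <= cx < n):
                continue
            if edt[cy, cx] < r_out + 1.0:
                continue
            ys = cy + dy
            xs = cx + dx
            # 1-px separation: check the blob grown by one pixel
            y0, y1 = ys.min() - 1, ys.max() + 2
            x0, x1 = xs.min() - 1, xs.max() + 2
            if y0 < 0 or x0 < 0 or y1 > n or x1 > n:
                continue
            patch = np.zeros((y1 - y0, x1 - x0), dtype=bool)
            patch[ys - y0, xs - x0] = True
            # full 3x3 structure: diagonal contact also merges 8-connected
            # components, so it must be excluded too
            grown = ndimage.binary_dilation(patch, structure=np.ones((3, 3), bool))
            if occupied[y0:y1, x0:x1][grown].any():
                continue
            masks[cls][ys, xs] = 1
            occupied[ys, xs] = True
            placed = True
            break
        if not placed:
            logger.warning(
                "skipped a %s-inflammation lesion of %d px after %d attempts",
                cls,
                size,
                config.max_placement_attempts,
            )
    return masks


def _lognormal_params(mean: float, std: float) -> tuple[float, float]:
    cv2 = (std / mean) ** 2
    sigma2 = float(np.log1p(cv2))
    mu = float(np.log(mean)) - 0.5 * sigma2
    return mu, float(np.sqrt(sigma2))


def _sample_lesion_sizes(
    config: PhantomConfig, cls: str, count: int, rng: np.random.Generator
) -> list[int]:
    if count == 0:
        return []
    mean = getattr(config, f"lesion_size_mean_{cls}")
    std = getattr(config, f"lesion_size_std_{cls}")
    mu, sig = _lognormal_params(mean, std)
    sizes = np.rint(rng.lognormal(mu, sig, size=count))
    sizes = np.clip(sizes, config.lesion_size_min, config.lesion_size_max)
    return [int(v) for v in sizes]


# --------------------------------------------------------------------------
# phantom generation
# --------------------------------------------------------------------------

def generate_phantom(
    config: PhantomConfig,
    patient: PatientState,
    view: str,
    rng: np.random.Generator,
) -> tuple[ScanImage, RawLabelSet]:
    """Generate one posed hand view and its raw (non-exclusive) labels.

    The raw normal mask is the full hand silhouette; lesion masks
    overlap it, exercising the non-exclusive annotation convention.
    """
    silhouette, loci = _hand_geometry(config, view, rng)

    specs: list[tuple[str, int]] = []
    for cls, flagged, rate, p_free in (
        ("low", patient.has_low, config.lesion_rate_low, config.p_image_free_low),
        ("high", patient.has_high, config.lesion_rate_high, config.p_image_free_high),
    ):
        count = 0
        if flagged and rng.random() >= p_free:
            count = int(rng.poisson(rate))
        specs.extend((cls, s) for s in _sample_lesion_sizes(config, cls, count, rng))
    lesions = _place_lesions(silhouette, loci, specs, config, rng)

    raw = RawLabelSet(
        normal=silhouette.astype(np.uint8),
        low=lesions["low"],
        high=lesions["high"],
    )

    intensity = np.full(silhouette.shape, config.lambda_background, dtype=float)
    intensity[silhouette] = config.lambda_normal
    intensity[lesions["low"] > 0] = config.lambda_low
    intensity[lesions["high"] > 0] = config.lambda_high
    blurred = ndimage.gaussian_filter(intensity, config.psf_sigma)
    counts = rng.poisson(blurred)
    display = np.clip(
        np.rint(counts * (config.display_max / config.count_scale_max)),
        0,
        config.display_max,
    ).astype(np.uint16)

    scan = ScanImage(pixels=display, patient_id=patient.patient_id, view=view)
    return scan, raw


def _proportional_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder allocation of ``n`` items to ``probs`` proportions."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def sample_patient_states(
    config: PhantomConfig, rng: np.random.Generator
) -> list[PatientState]:
    """Assign each patient an inflammation state once (shared across views).

    The cohort being emulated is a single fixed dataset whose composition
    statistics are known, not a draw from a superpopulation, so the four
    patient states (healthy / low-only / high-only / both) are allocated
    in fixed proportions by largest remainder and shuffled across
    patients; only the assignment, not the composition, is random.
    """
    p_both = config.p_patient_has_both
    p_low_only = config.p_patient_has_low - p_both
    p_high_only = config.p_patient_has_high - p_both
    p_none = 1.0 - p_both - p_low_only - p_high_only
    probs = np.array([p_none, p_low_only, p_high_only, p_both])
    counts = _proportional_counts(probs / probs.sum(), config.n_patients)
    states = rng.permutation(np.repeat(np.arange(4), counts))
    width = max(3, len(str(config.n_patients)))
    return [
        PatientState(
            patient_id=f"P{idx:0{width}d}",
            has_low=state in (1, 3),
            has_high=state in (2, 3),
        )
        for idx, state in enumerate(states, start=1)
    ]


def generate_cohort(config: PhantomConfig) -> Cohort:
    """Seeded cohort of n_patients x views_per_patient phantom scans."""
    rng = np.random.default_rng(config.seed)
    patients = sample_patient_states(config, rng)
    records = []
    for patient in patients:
        for view in VIEWS[: config.views_per_patient]:
            scan, raw = generate_phantom(config, patient, view, rng)
            records.append(
                CohortRecord(
                    image_id=f"{patient.patient_id}_{view}",
                    patient_id=patient.patient_id,
                    view=view,
                    scan=scan,
                    raw=raw,
                    fused=fuse_labels(raw),
                )
            )
    return Cohort(config=config, patients=patients, records=records)


# --------------------------------------------------------------------------
# cohort statistics
# --------------------------------------------------------------------------

@dataclass
class CohortStats:
    """Printed-statistic analogues computed from fused labels."""

    n_images: int
    pixel_fraction: dict[str, float]
    empty_mask_images: dict[str, int]
    images_with_neither: int
    lesion_size_mean: dict[str, float]
    lesion_size_std: dict[str, float]
    n_lesions: dict[str, int]

    def to_dict(self) -> dict:
        return asdict(self)


def lesion_component_sizes(fused: np.ndarray, class_code: int) -> np.ndarray:
    """Pixel counts of the 8-connected components of one class."""
    mask = np.asarray(fused) == class_code
    if not mask.any():
        return np.array([], dtype=int)
    comps = cc_label(mask, connectivity=2)
    return np.bincount(comps.ravel())[1:]


def cohort_statistics(cohort: Cohort | Sequence[CohortRecord]) -> CohortStats:
    """Per-class pixel fractions, empty-image counts and lesion sizes."""
    records = list(cohort)
    if not records:
        raise ValueError("cohort is empty")
    class_codes = {"normal": _labels.NORMAL, "low": _labels.LOW, "high": _labels.HIGH}
    total_px = 0
    class_px = {c: 0 for c in class_codes}
    empty = {c: 0 for c in class_codes}
    neither = 0
    sizes: dict[str, list[np.ndarray]] = {"low": [], "high": []}
    for rec in records:
        fused = rec.fused
        total_px += fused.size
        any_inflamed = False
        for cls, code in class_codes.items():
            n = int(np.count_nonzero(fused == code))
            class_px[cls] += n
            if n == 0:
                empty[cls] += 1
            elif cls in ("low", "high"):
                any_inflamed = True
        if not any_inflamed:
            neither += 1
        for cls in ("low", "high"):
            s = lesion_component_sizes(fused, class_codes[cls])
            if s.size:
                sizes[cls].append(s)
    mean = {}
    std = {}
    counts = {}
    for cls in ("low", "high"):
        pooled = np.concatenate(sizes[cls]) if sizes[cls] else np.array([])
        counts[cls] = int(pooled.size)
        mean[cls] = float(pooled.mean()) if pooled.size else float("nan")
        std[cls] = float(pooled.std(ddof=1)) if pooled.size > 1 else float("nan")
    return CohortStats(
        n_images=len(records),
        pixel_fraction={c: class_px[c] / total_px for c in class_codes},
        empty_mask_images=empty,
        images_with_neither=neither,
        lesion_size_mean=mean,
        lesion_size_std=std,
        n_lesions=counts,
    )
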