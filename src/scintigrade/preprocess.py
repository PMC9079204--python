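"""Preprocessing: anterior-view selection, thoracic cropping, log transform
and pixel-wise z-score normalisation.

Whole-body images are cropped to a 128 x 128 thoracic window: the window's
upper edge sits at 0.85 x patient height measured up from the patient's
lowest nonzero row, its lower edge 128 pixels below, and its columns span
64 pixels either side of the image centre. Planar images are downsampled to
256 x 256 (block average) if larger and centre-cropped to 128 x 128. All
nonzero intensities are then log-transformed, x -> ln(1 + x), which
compresses focal hot spots (injection site, metastatic lesions) that would
otherwise dominate the intensity range. Finally images are z-scored
pixel-wise against statistics of the training set only.

All geometry uses 0-based indices, row 0 cranial, windows half-open
``[top, top + 128)``. Fractional coordinates round half away from zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize_local_mean
from sklearn.base import BaseEstimator, TransformerMixin

from .phantom import ScintigraphyStudy

logger = logging.getLogger(__name__)

CROP_SIZE = 128
CROP_FRACTION = 0.85
PLANAR_TARGET = 256

__all__ = [
    "CropWindow",
    "PreprocessedImage",
    "NormalizationStats",
    "select_anterior",
    "locate_patient_extent",
    "whole_body_window",
    "apply_window",
    "crop_whole_body",
    "crop_planar",
    "log_transform",
    "compute_norm_stats",
    "zscore_apply",
    "preprocess_study",
    "preprocess_studies",
    "ZScoreNormalizer",
]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class CropWindow:
    """A 128 x 128 crop location; may extend past the source image, in which
    case :func:`apply_window` zero-pads the missing part."""

    top_row: int
    left_col: int
    size: int = CROP_SIZE


@dataclass
class PreprocessedImage:
    """A 128 x 128 matrix ready for the CNN, plus carried-over labels."""

    pixels: np.ndarray
    source_id: str = ""
    grade: int = 0
    has_metastases: bool = False
    window: CropWindow | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (CROP_SIZE, CROP_SIZE):
            raise ValueError(f"expected {CROP_SIZE}x{CROP_SIZE}, got {self.pixels.shape}")


@dataclass
class NormalizationStats:
    """Per-pixel training-set mean and standard deviation."""

    mean_image: np.ndarray
    std_image: np.ndarray
    epsilon: float = 1e-7


def select_anterior(studies: list[ScintigraphyStudy]) -> list[ScintigraphyStudy]:
    """Retain only anterior (AP) studies, order preserved."""
    return [s for s in studies if s.view == "AP"]


def locate_patient_extent(image: np.ndarray) -> tuple[int, int]:
    """First and last row whose count sum is positive (the y line profile)."""
    image = np.asarray(image)
    rows = np.nonzero(image.sum(axis=1) > 0)[0]
    if rows.size == 0:
        raise ValueError("no patient detected: image is all zero")
    return int(rows[0]), int(rows[-1])


def whole_body_window(image: np.ndarray,
                      crop_fraction: float = CROP_FRACTION,
                      column_center: str = "geometric") -> CropWindow:
    """Thoracic crop window for a whole-body image.

    With patient height ``H = bottom - top + 1``, the window top row is
    ``round(bottom - crop_fraction * H)`` (measuring 0.85 x patient height up
    from the lowest nonzero row places the window over the thorax), clamped
    to the image. Columns span ``center - 64 .. center + 63`` where the
    centre is the geometric image centre (or the patient's nonzero-column
    centre with ``column_center='patient'``).
    """
    image = np.asarray(image)
    n_rows, n_cols = image.shape
    top, bottom = locate_patient_extent(image)
    height = bottom - top + 1
    win_top = _round_half_away(bottom - crop_fraction * height)
    if n_rows >= CROP_SIZE:
        win_top = min(max(win_top, 0), n_rows - CROP_SIZE)
    else:
        logger.warning("image has %d rows < %d; crop will be zero-padded",
                       n_rows, CROP_SIZE)
    if column_center == "patient":
        cols = np.nonzero(image.sum(axis=0) > 0)[0]
        center = int(cols.mean()) if cols.size else n_cols // 2
    else:
        center = n_cols // 2
    win_left = center - CROP_SIZE // 2
    if n_cols >= CROP_SIZE:
        win_left = min(max(win_left, 0), n_cols - CROP_SIZE)
    else:
        logger.warning("image has %d cols < %d; crop will be zero-padded",
                       n_cols, CROP_SIZE)
        win_left = -((CROP_SIZE - n_cols) // 2)  # symmetric zero padding
    return CropWindow(win_top, win_left)


def apply_window(image: np.ndarray, window: CropWindow) -> np.ndarray:
    """Extract the window, zero-padding any part outside the image."""
    image = np.asarray(image)
    k = window.size
    out = np.zeros((k, k), dtype=np.float64)
    r0, c0 = window.top_row, window.left_col
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + k, image.shape[0]), min(c0 + k, image.shape[1])
    if re > rs and ce > cs:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = image[rs:re, cs:ce]
    return out


def crop_whole_body(image: np.ndarray, **kwargs) -> np.ndarray:
    """128 x 128 thoracic crop of a whole-body image."""
    return apply_window(image, whole_body_window(image, **kwargs))


def crop_planar(image: np.ndarray) -> np.ndarray:
    """Centre 128 x 128 crop of a planar image, after block-average
    downsampling to 256 x 256 when either dimension exceeds 256."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if h > PLANAR_TARGET or w > PLANAR_TARGET:
        image = resize_local_mean(image, (PLANAR_TARGET, PLANAR_TARGET))
        h, w = image.shape
    if h < CROP_SIZE or w < CROP_SIZE:
        logger.warning("planar image %dx%d smaller than crop; zero-padding", h, w)
        ph, pw = max(CROP_SIZE - h, 0), max(CROP_SIZE - w, 0)
        image = np.pad(image, ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)))
        h, w = image.shape
    r0, c0 = (h - CROP_SIZE) // 2, (w - CROP_SIZE) // 2
    return image[r0 : r0 + CROP_SIZE, c0 : c0 + CROP_SIZE]


def log_transform(image: np.ndarray) -> np.ndarray:
    """Elementwise x -> ln(1 + x); zeros map to zero, order is preserved."""
    image = np.asarray(image, dtype=np.float64)
    if (image < 0).any():
        raise ValueError("negative counts are invalid")
    return np.log1p(image)


def compute_norm_stats(train_images, epsilon: float = 1e-7) -> NormalizationStats:
    """Per-pixel mean/std over the training images only (>= 2 required)."""
    arrs = np.stack([_pixels(im) for im in train_images])
    if arrs.shape[0] < 2:
        raise ValueError("need at least 2 training images for normalisation stats")
    return NormalizationStats(arrs.mean(axis=0), arrs.std(axis=0), epsilon)


def zscore_apply(image, stats: NormalizationStats) -> np.ndarray:
    """Pixel-wise ``(x - mean) / max(std, epsilon)``."""
    x = _pixels(image)
    if x.shape != stats.mean_image.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {stats.mean_image.shape}")
    return (x - stats.mean_image) / np.maximum(stats.std_image, stats.epsilon)


def _pixels(im) -> np.ndarray:
    return im.pixels if isinstance(im, PreprocessedImage) else np.asarray(im, dtype=np.float64)


def preprocess_study(study: ScintigraphyStudy, **kwargs) -> PreprocessedImage:
    """Crop (by protocol) and log-transform one anterior study."""
    if study.protocol == "whole_body":
        window = whole_body_window(study.pixels, **kwargs)
        cropped = apply_window(study.pixels, window)
    else:
        cropped = crop_planar(study.pixels)
        window = None
    return PreprocessedImage(
        pixels=log_transform(cropped),
        source_id=study.study_id,
        grade=study.grade,
        has_metastases=study.has_metastases,
        window=window,
    )


def preprocess_studies(studies, keep_anterior_only: bool = True,
                       **kwargs) -> list[PreprocessedImage]:
    """Full deterministic preprocessing of a list of studies."""
    if keep_anterior_only:
        studies = select_anterior(studies)
    return [preprocess_study(s, **kwargs) for s in studies]


class ZScoreNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style pixel-wise z-score transformer.

    ``fit`` learns per-pixel mean and std from the training images (an
    array of shape ``(n, H, W)`` or a list of :class:`PreprocessedImage`);
    ``transform`` applies ``(x - mean_) / max(std_, epsilon)``. Keeping the
    statistics inside a fitted transformer makes train-only dependence
    explicit and composable with sklearn pipelines.
    """

    def __init__(self, epsilon: float = 1e-7):
        self.epsilon = epsilon

    def fit(self, X, y=None):
        X = self._as_array(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training images")
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def transform(self, X):
        X = self._as_array(X)
        if X.shape[1:] != self.mean_.shape:
            raise ValueError(f"shape mismatch: {X.shape[1:]} vs {self.mean_.shape}")
        return (X - self.mean_) / np.maximum(self.std_, self.epsilon)

    def stats(self) -> NormalizationStats:
        return NormalizationStats(self.mean_, self.std_, self.epsilon)

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, np.ndarray):
            return X.astype(np.float64, copy=False)
        return np.stack([_pixels(im) for im in X])
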