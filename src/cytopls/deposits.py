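"""Pixel-neighborhood quantification of concentrated fluorescence deposits.

Input images are grayscale intensity grids exported as ImageJ "text images"
(tab-delimited integer matrices), with background and excluded regions set
to 0 upstream.  Each non-background pixel is classified TRUE when its own
intensity and the intensities of *all* of its existing 8-connected
neighbors exceed a threshold (interior pixels have 8 neighbors, non-corner
edge pixels 5, corner pixels 3), FALSE otherwise.  The deposit statistic is
the percentage of TRUE pixels among TRUE + FALSE, which separates
concentrated deposits (large contiguous supra-threshold regions) from
diffuse staining at the same mean brightness.

"Above threshold" is strict; background pixels (value 0) adjacent to a
candidate always fail the neighbor condition, so signal bordering background
is FALSE.  No padding is used at the image boundary: missing neighbors are
simply not required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.ndimage import maximum_filter, minimum_filter, uniform_filter

__all__ = [
    "DEFAULT_THRESHOLD",
    "PixelLabel",
    "DepositResult",
    "DepositError",
    "read_text_image",
    "write_text_image",
    "classify_deposit_pixels",
    "deposit_fraction",
    "quantify_deposits",
    "derive_threshold",
    "roi_mean_intensity",
    "neighbor_counts",
]

DEFAULT_THRESHOLD = 73.0  # intensity units, instrument scale


class DepositError(ValueError):
    """Raised on malformed images, masks or thresholds."""


class PixelLabel(IntEnum):
    BACKGROUND = 0
    FALSE = 1
    TRUE = 2


@dataclass(frozen=True)
class DepositResult:
    """Counts and percentage of TRUE pixels for one image."""

    percent_true: float
    n_true: int
    n_false: int
    n_background: int
    threshold_used: float


def read_text_image(path) -> np.ndarray:
    """Parse an ImageJ text image (tab/space-delimited intensity matrix).

    Returns an H x W integer array with row/column order preserved.  Rows
    must be rectangular; values must be nonnegative.  Non-integer values are
    rounded half-up with a warning (text exports are occasionally float-
    formatted).
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise DepositError(f"row {lineno}: non-numeric entry") from exc
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise DepositError(
                    f"row {lineno}: ragged row ({len(rows[-1])} values, "
                    f"expected {len(rows[0])})"
                )
    if not rows:
        raise DepositError("empty image file")
    grid = np.array(rows, dtype=float)
    if (grid < 0).any():
        raise DepositError("negative intensity value")
    rounded = np.floor(grid + 0.5)
    if not np.array_equal(rounded, grid):
        warnings.warn("non-integer intensities rounded half-up", stacklevel=2)
    return rounded.astype(np.int64)


def write_text_image(image: np.ndarray, path) -> None:
    """Write an intensity grid in the tab-delimited text-image format."""
    image = np.asarray(image)
    with open(path, "w") as fh:
        for row in image:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise DepositError("image must be a non-empty 2-D grid")
    if (image < 0).any():
        raise DepositError("image intensities must be >= 0")
    return image


def neighbor_counts(shape: tuple[int, int]) -> np.ndarray:
    """Number of existing 8-connected neighbors of each pixel.

    Interior pixels have 8, non-corner edge pixels 5, corner pixels 3 (and
    degenerate single-row/column images correspondingly fewer).
    """
    H, W = shape
    ones = np.ones((H, W))
    # window sum counts the pixel itself; subtract it
    counts = uniform_filter(ones, size=3, mode="constant", cval=0.0) * 9 - 1
    return np.rint(counts).astype(int)


def classify_deposit_pixels(
    image: np.ndarray, threshold: float = DEFAULT_THRESHOLD, *, require_all: bool = True
) -> np.ndarray:
    """Label each pixel BACKGROUND / TRUE / FALSE by the neighborhood rule.

    A pixel with value 0 is BACKGROUND.  Otherwise it is TRUE when its own
    value is strictly above ``threshold`` and — with the default
    ``require_all`` — every existing 8-connected neighbor is too (a pixel
    with no neighbors satisfies the condition vacuously).  With
    ``require_all=False`` a single supra-threshold neighbor suffices (non-
    default variant).  Background neighbors count as not-above-threshold.
    """
    image = _validate_image(image)
    if not threshold > 0:
        raise DepositError("threshold must be > 0")
    above = (image > threshold).astype(np.uint8)
    if require_all:
        # cval=1: out-of-bounds neighbors are vacuously above threshold
        hot = minimum_filter(above, size=3, mode="constant", cval=1).astype(bool)
    else:
        neigh = maximum_filter(
            above, footprint=np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]),
            mode="constant", cval=0,
        ).astype(bool)
        hot = above.astype(bool) & (neigh | (neighbor_counts(image.shape) == 0))
    labels = np.where(hot, PixelLabel.TRUE, PixelLabel.FALSE).astype(np.int8)
    labels[image == 0] = PixelLabel.BACKGROUND
    return labels


def deposit_fraction(
    labels: np.ndarray, threshold_used: float = DEFAULT_THRESHOLD
) -> DepositResult:
    """Percentage of TRUE pixels over TRUE + FALSE (background excluded)."""
    labels = np.asarray(labels)
    n_true = int((labels == PixelLabel.TRUE).sum())
    n_false = int((labels == PixelLabel.FALSE).sum())
    n_background = int((labels == PixelLabel.BACKGROUND).sum())
    if n_true + n_false == 0:
        raise DepositError("all-background image: deposit fraction undefined")
    return DepositResult(
        percent_true=100.0 * n_true / (n_true + n_false),
        n_true=n_true,
        n_false=n_false,
        n_background=n_background,
        threshold_used=float(threshold_used),
    )


def quantify_deposits(
    image: np.ndarray, threshold: float = DEFAULT_THRESHOLD, *, require_all: bool = True
) -> DepositResult:
    """Classify and summarize in one call."""
    labels = classify_deposit_pixels(image, threshold, require_all=require_all)
    return deposit_fraction(labels, threshold_used=threshold)


def derive_threshold(
    region_means=None, *, default: float | None = DEFAULT_THRESHOLD
) -> float:
    """Average the mean intensities of reference deposit regions.

    The pipeline threshold is the arithmetic mean of the mean fluorescence
    intensities measured over the largest deposits of the reference images;
    with no regions supplied the published default (73) is returned.
    """
    if region_means is not None and len(region_means):
        return float(np.mean(np.asarray(region_means, dtype=float)))
    if default is None:
        raise DepositError("no reference regions and no default threshold")
    return float(default)


def roi_mean_intensity(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean intensity over an externally supplied region-of-interest mask.

    The mask (same shape, truthy = included) encodes a manually drawn
    outline with tears/pockets excluded; this package does not segment.
    """
    image = _validate_image(image)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.shape:
        raise DepositError("mask shape does not match image")
    if not mask.any():
        raise DepositError("empty ROI mask")
    return float(image[mask].mean())
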