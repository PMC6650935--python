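"""Region-of-interest extraction from raw sample images.

A raw scan shows a bright flour portion on a dark background.  The ROI is
found by Otsu thresholding of the intensity channel, hole filling, locating
the foreground center of mass, and growing the largest all-foreground
square around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class DegenerateSegmentationError(ValueError):
    """Raised when an image cannot be segmented (e.g. constant intensity)."""


class ROITooSmallError(ValueError):
    """Raised when the grown square is too small to survive two halvings."""


MIN_ROI_SIDE = 8


@dataclass
class RGBImage:
    """An 8-bit RGB raster with sample provenance.

    Parameters
    ----------
    pixels : ndarray of shape (H, W, 3)
        Channel intensities in [0, 255].
    sample_id : str
        Unique identifier of the physical sample.
    cultivar_id : str
        Identifier of the cultivar (subject group) the sample belongs to.
    label : str
        Class tag, ``"malting"``, ``"naked"`` or ``"unknown"``.
    """

    pixels: np.ndarray
    sample_id: str = ""
    cultivar_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixels, got shape {px.shape}")
        if px.shape[0] < MIN_ROI_SIDE or px.shape[1] < MIN_ROI_SIDE:
            raise ValueError(
                f"image {self.sample_id!r} is {px.shape[0]}x{px.shape[1]}; "
                f"minimum side is {MIN_ROI_SIDE}"
            )
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class BinaryMask:
    """A boolean foreground mask with the same shape as its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected 2-D mask, got shape {px.shape}")
        self.pixels = px.astype(bool)

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class ROI:
    """A square crop of a parent image, with its location recorded."""

    pixels: np.ndarray
    origin: tuple[int, int]
    side: int = field(default=0)
    sample_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[0] != px.shape[1]:
            raise ValueError(f"ROI must be square H x H x 3, got {px.shape}")
        self.pixels = px
        self.side = px.shape[0]


def to_monochrome(img: RGBImage | np.ndarray) -> np.ndarray:
    """Convert an RGB image to intensity: the per-pixel mean of R, G, B."""
    px = img.pixels if isinstance(img, RGBImage) else np.asarray(img)
    return px.astype(np.float64).mean(axis=2)


def otsu_threshold(grey: np.ndarray, sample_id: str = "") -> int:
    """Otsu threshold over the 256-bin histogram of an intensity image.

    Returns the threshold ``t`` maximizing between-class variance of the
    split into values ``<= t`` versus ``> t``; ties broken by smallest t.

    Raises
    ------
    DegenerateSegmentationError
        If the image is constant (no split has two nonempty classes).
    """
    grey = np.asarray(grey, dtype=np.float64)
    hist, _ = np.histogram(grey, bins=256, range=(0.0, 256.0))
    hist = hist.astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateSegmentationError(
            f"cannot segment constant image (sample {sample_id!r})"
        )
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                    # pixels at level <= t
    m0 = np.cumsum(hist * levels)           # intensity mass at level <= t
    w1 = n - w0
    mu_total = m0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (mu_total - m0) / w1
        sigma_b = w0 * w1 * (mean0 - mean1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -1.0   # one-class splits never win
    return int(np.argmax(sigma_b))          # argmax takes the smallest tie


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill background components not connected to the border (4-connectivity)."""
    if mask.count == 0:
        raise ValueError("cannot fill holes of an all-background mask")
    structure = ndimage.generate_binary_structure(2, 1)  # 4-connected flood
    filled = ndimage.binary_fill_holes(mask.pixels, structure=structure)
    return BinaryMask(filled)


def center_of_mass(mask: BinaryMask) -> tuple[float, float]:
    """Arithmetic mean of foreground pixel coordinates."""
    if mask.count == 0:
        raise ValueError("center of mass undefined for empty mask")
    r, c = ndimage.center_of_mass(mask.pixels)
    return float(r), float(c)


def grow_square(mask: BinaryMask, center: tuple[float, float]) -> tuple[int, int, int]:
    """Grow the largest all-foreground square around ``center``.

    The candidate square of side ``s`` is centered on the rounded center as
    nearly as parity allows and clamped inside the image; the side grows
    while every covered pixel is foreground.

    Returns
    -------
    (row0, col0, side) of the final square.

    Raises
    ------
    ValueError
        If the rounded center lies on background.
    """
    px = mask.pixels
    h, w = px.shape
    ci = int(np.clip(round(center[0]), 0, h - 1))
    cj = int(np.clip(round(center[1]), 0, w - 1))
    if not px[ci, cj]:
        raise ValueError(f"center ({ci}, {cj}) lies on background")

    best = (ci, cj, 1)
    for s in range(2, min(h, w) + 1):
        r0 = int(np.clip(ci - s // 2, 0, h - s))
        c0 = int(np.clip(cj - s // 2, 0, w - s))
        if px[r0 : r0 + s, c0 : c0 + s].all():
            best = (r0, c0, s)
        else:
            break
    return best


def extract_roi(img: RGBImage, invert_foreground: bool = False) -> ROI:
    """Full ROI pipeline: threshold, fill holes, center, grow square, crop.

    Foreground is assumed brighter than the background; pass
    ``invert_foreground=True`` for dark objects on a bright background.
    """
    grey = to_monochrome(img)
    t = otsu_threshold(grey, sample_id=img.sample_id)
    fg = grey <= t if invert_foreground else grey > t
    mask = fill_holes(BinaryMask(fg))
    com = center_of_mass(mask)
    r0, c0, side = grow_square(mask, com)
    if side < MIN_ROI_SIDE:
        raise ROITooSmallError(
            f"ROI side {side} < {MIN_ROI_SIDE} for sample {img.sample_id!r}"
        )
    crop = img.pixels[r0 : r0 + side, c0 : c0 + side].copy()
    return ROI(pixels=crop, origin=(r0, c0), sample_id=img.sample_id)
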