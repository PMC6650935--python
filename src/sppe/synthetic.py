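"""Synthetic flour-image generator.

Produces labeled two-class image sets that mimic the structure of a
scanned flour dataset: bright granular foreground on a dark background,
per-cultivar color offsets, per-pixel granular noise, and dark elongated
"husk" speckles whose density differs by class.  Everything is driven by
one seed so generated datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color as skcolor
from skimage.draw import ellipse
from skimage.filters import gaussian

from sppe.preprocess import RGBImage, ROI

CLASSES = ("malting", "naked")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic dataset.

    Defaults reproduce the reference design: 5 images for each of
    14 malting + 8 naked cultivars = 110 images (70 / 40 per class).
    """

    n_cultivars_malting: int = 14
    n_cultivars_naked: int = 8
    images_per_cultivar: int = 5
    image_side: int = 256
    #: class mean colors as L*, a*, b* triples
    malting_lab: tuple[float, float, float] = (68.0, 5.0, 19.0)
    naked_lab: tuple[float, float, float] = (74.0, 2.0, 13.0)
    #: std of the per-cultivar L*a*b* offset
    cultivar_offset_sigma: float = 1.0
    #: std of per-pixel granular noise in L*a*b* units
    grain_noise_sigma: float = 2.5
    #: husk speckles per 10^4 foreground pixels, per class
    husk_density_malting: float = 2.0
    husk_density_naked: float = 0.5
    #: (min, max) of husk semi-major and semi-minor axes, pixels
    husk_length: tuple[float, float] = (3.0, 7.0)
    husk_width: tuple[float, float] = (0.8, 1.8)
    background_margin: int = 16
    background_grey: int = 8
    #: place one naked cultivar's color inside the malting color region
    hard_cultivar: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cultivars_malting",
            "n_cultivars_naked",
            "images_per_cultivar",
            "image_side",
            "background_margin",
        ):
            if getattr(self, name) < 0 or (
                name != "background_margin" and getattr(self, name) <= 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.husk_density_malting < 0 or self.husk_density_naked < 0:
            raise ValueError("husk densities must be >= 0")
        if self.grain_noise_sigma < 0 or self.cultivar_offset_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.image_side < 8:
            raise ValueError("image_side must be >= 8")


def _lab_to_uint8(lab: np.ndarray) -> np.ndarray:
    rgb = skcolor.lab2rgb(lab)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def _stamp_husks(
    lab: np.ndarray,
    rng: np.random.Generator,
    density: float,
    length: tuple[float, float],
    width: tuple[float, float],
) -> None:
    """Stamp Poisson-many dark elongated ellipses into a L*a*b* raster."""
    h, w = lab.shape[:2]
    n = rng.poisson(density * h * w / 1e4)
    for _ in range(n):
        r0 = rng.uniform(0, h)
        c0 = rng.uniform(0, w)
        a = rng.uniform(*length)
        b = rng.uniform(*width)
        theta = rng.uniform(0, np.pi)
        rr, cc = ellipse(r0, c0, a, b, shape=(h, w), rotation=theta)
        if rr.size == 0:
            continue
        # dark brownish fragment
        lab[rr, cc, 0] = 28.0 + rng.normal(0, 2.0)
        lab[rr, cc, 1] = 8.0
        lab[rr, cc, 2] = 16.0


def _render_image(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    base_lab: np.ndarray,
    density: float,
) -> np.ndarray:
    side = cfg.image_side
    lab = np.empty((side, side, 3), dtype=np.float64)
    lab[:] = base_lab
    if cfg.grain_noise_sigma > 0:
        lab += rng.normal(0.0, cfg.grain_noise_sigma, size=lab.shape)
    if density > 0:
        _stamp_husks(lab, rng, density, cfg.husk_length, cfg.husk_width)
    inner = _lab_to_uint8(lab)
    m = cfg.background_margin
    if m == 0:
        return inner
    canvas = np.full(
        (side + 2 * m, side + 2 * m, 3), cfg.background_grey, dtype=np.uint8
    )
    canvas[m : m + side, m : m + side] = inner
    return canvas


def generate_dataset(cfg: GeneratorConfig) -> tuple[list[RGBImage], pd.DataFrame]:
    """Generate the full labeled image set and its manifest.

    Returns the images and a manifest DataFrame with columns
    ``sample_id, cultivar_id, label`` (plus ``path`` once written to disk).
    """
    rng = np.random.default_rng(cfg.seed)
    class_plan = [
        ("malting", "M", cfg.n_cultivars_malting, cfg.husk_density_malting),
        ("naked", "N", cfg.n_cultivars_naked, cfg.husk_density_naked),
    ]
    class_mean = {
        "malting": np.asarray(cfg.malting_lab, dtype=np.float64),
        "naked": np.asarray(cfg.naked_lab, dtype=np.float64),
    }
    images: list[RGBImage] = []
    rows = []
    for label, prefix, n_cultivars, density in class_plan:
        for c in range(1, n_cultivars + 1):
            cultivar_id = f"{prefix}{c:02d}"
            offset = rng.normal(0.0, cfg.cultivar_offset_sigma, size=3)
            if cfg.hard_cultivar and cultivar_id == "N07":
                # a naked cultivar whose color sits inside the malting cloud
                offset = class_mean["malting"] - class_mean["naked"] + rng.normal(
                    0.0, 0.25 * cfg.cultivar_offset_sigma, size=3
                )
            base = class_mean[label] + offset
            for k in range(1, cfg.images_per_cultivar + 1):
                sample_id = f"{cultivar_id}_{k}"
                pixels = _render_image(cfg, rng, base, density)
                images.append(
                    RGBImage(
                        pixels=pixels,
                        sample_id=sample_id,
                        cultivar_id=cultivar_id,
                        label=label,
                    )
                )
                rows.append(
                    {"sample_id": sample_id, "cultivar_id": cultivar_id, "label": label}
                )
    return images, pd.DataFrame(rows)


def _quadrant_bounds(h: int, w: int, quadrant: int) -> tuple[int, int, int, int]:
    hr, hc = h // 2, w // 2
    bounds = {
        0: (0, hr, 0, hc),
        1: (0, hr, hc, w),
        2: (hr, h, 0, hc),
        3: (hr, h, hc, w),
    }
    return bounds[quadrant]


def localized_artifact(
    img: RGBImage | ROI,
    quadrant: int,
    kind: str = "speckle",
    seed: int = 0,
    density: float = 40.0,
) -> RGBImage | ROI:
    """Corrupt exactly one level-1 quadrant of an image; the rest is untouched.

    kind "speckle" stamps dense dark elongated fragments; "blur" applies a
    Gaussian blur.  Quadrants are row-major 0..3 with a floor split, so the
    corrupted area coincides with one level-1 pyramid tile.
    """
    if quadrant not in (0, 1, 2, 3):
        raise ValueError(f"quadrant must be in 0..3, got {quadrant}")
    if kind not in ("speckle", "blur"):
        raise ValueError(f"kind must be 'speckle' or 'blur', got {kind!r}")
    rng = np.random.default_rng(seed)
    px = img.pixels.copy()
    r0, r1, c0, c1 = _quadrant_bounds(px.shape[0], px.shape[1], quadrant)
    patch = px[r0:r1, c0:c1].astype(np.float64)
    if kind == "speckle":
        lab = skcolor.rgb2lab(patch / 255.0)
        _stamp_husks(lab, rng, density, (4.0, 9.0), (1.0, 2.5))
        patch = _lab_to_uint8(lab)
    else:
        patch = np.clip(
            np.round(gaussian(patch, sigma=3.0, channel_axis=-1)), 0, 255
        ).astype(np.uint8)
    px[r0:r1, c0:c1] = patch
    if isinstance(img, ROI):
        return ROI(pixels=px, origin=img.origin, sample_id=img.sample_id)
    return RGBImage(
        pixels=px,
        sample_id=img.sample_id,
        cultivar_id=img.cultivar_id,
        label=img.label,
    )
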