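"""End-to-end helpers wiring preprocessing, partitioning and features."""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from sppe.ensemble import extract_features
from sppe.preprocess import RGBImage, extract_roi
from sppe.pyramid import PyramidSet, partition


def image_to_pyramid(img: RGBImage, invert_foreground: bool = False) -> PyramidSet:
    """ROI extraction followed by the 3-level pyramid partition."""
    return partition(extract_roi(img, invert_foreground=invert_foreground))


def images_to_table(
    images: Iterable[RGBImage], invert_foreground: bool = False
) -> pd.DataFrame:
    """Full feature table (21 rows per sample) from raw images."""
    images = list(images)
    pyramids = [image_to_pyramid(im, invert_foreground) for im in images]
    labels = {im.sample_id: im.label for im in images}
    cultivars = {im.sample_id: im.cultivar_id for im in images}
    return extract_features(pyramids, labels=labels, cultivars=cultivars)
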