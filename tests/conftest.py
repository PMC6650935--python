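from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sppe.features import FEATURE_NAMES
from sppe.pipeline import images_to_table
from sppe.synthetic import GeneratorConfig, generate_dataset


def grey_region(values: np.ndarray) -> np.ndarray:
    """Stack a 2-D grey array into an H x W x 3 RGB region."""
    v = np.asarray(values)
    return np.repeat(v[..., None], 3, axis=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_cultivars_malting=3,
        n_cultivars_naked=3,
        images_per_cultivar=2,
        image_side=64,
        background_margin=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_images(small_config):
    images, manifest = generate_dataset(small_config)
    return images, manifest


@pytest.fixture(scope="session")
def small_table(small_images) -> pd.DataFrame:
    images, _ = small_images
    return images_to_table(images)


def synthetic_region_table(
    n_samples: int = 6, sep: float = 10.0, noise: float = 0.5, seed: int = 0
) -> pd.DataFrame:
    """A hand-built region table (21 rows/sample) with a clean class shift.

    Avoids image rendering entirely; used where only the learning machinery
    is under test.
    """
    rs = np.random.default_rng(seed)
    rows = []
    for s in range(n_samples):
        label = "malting" if s % 2 == 0 else "naked"
        shift = 0.0 if label == "malting" else sep
        sid = f"S{s:02d}"
        for level, count in ((0, 1), (1, 4), (2, 16)):
            for tile in range(count):
                vals = rs.normal(shift, noise, size=len(FEATURE_NAMES))
                rec = dict(zip(FEATURE_NAMES, vals))
                rec.update(
                    sample_id=sid,
                    cultivar_id=f"C{s % 4}",
                    level=level,
                    tile_index=tile,
                    label=label,
                )
                rows.append(rec)
    return pd.DataFrame(rows)


@pytest.fixture
def region_table() -> pd.DataFrame:
    return synthetic_region_table()
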