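"""Three-level spatial pyramid partition of a square ROI.

Level 0 is the ROI itself; level 1 quarters it; level 2 quarters each
level-1 tile, giving 21 regions in a fixed, reproducible order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sppe.preprocess import ROI, MIN_ROI_SIDE

#: Number of regions per pyramid: 1 (level 0) + 4 (level 1) + 16 (level 2).
N_REGIONS = 21
#: Number of voting members per sample (levels 1 and 2 only).
N_VOTERS = 20
LEVEL_SIZES = {0: 1, 1: 4, 2: 16}


@dataclass
class Region:
    """A sub-raster of a ROI tagged with its pyramid position."""

    pixels: np.ndarray
    level: int
    tile_index: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.level not in LEVEL_SIZES:
            raise ValueError(f"level must be 0, 1 or 2, got {self.level}")
        if not 0 <= self.tile_index < LEVEL_SIZES[self.level]:
            raise ValueError(
                f"tile_index {self.tile_index} out of range for level {self.level}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class PyramidSet:
    """The 21 regions of one ROI, ordered level-ascending then row-major.

    Level-2 tiles are grouped by parent level-1 tile: tile index
    ``4 * parent + quadrant`` with quadrants in row-major order.
    """

    regions: list[Region]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.regions) != N_REGIONS:
            raise ValueError(f"expected {N_REGIONS} regions, got {len(self.regions)}")

    def level(self, lv: int) -> list[Region]:
        return [r for r in self.regions if r.level == lv]

    @property
    def voters(self) -> list[Region]:
        """The 20 level-1/2 regions participating in the weighted vote."""
        return [r for r in self.regions if r.level >= 1]


def _quarter(arr: np.ndarray) -> list[np.ndarray]:
    """Split an array into 4 row-major quadrants with a floor split."""
    h, w = arr.shape[0], arr.shape[1]
    hr, hc = h // 2, w // 2
    return [
        arr[:hr, :hc],
        arr[:hr, hc:],
        arr[hr:, :hc],
        arr[hr:, hc:],
    ]


def partition(roi: ROI) -> PyramidSet:
    """Split a ROI into its 21-region spatial pyramid."""
    if roi.side < MIN_ROI_SIDE:
        raise ValueError(f"ROI side {roi.side} < {MIN_ROI_SIDE}")
    sid = roi.sample_id
    regions = [Region(roi.pixels, level=0, tile_index=0, sample_id=sid)]
    level1 = _quarter(roi.pixels)
    for i, tile in enumerate(level1):
        regions.append(Region(tile, level=1, tile_index=i, sample_id=sid))
    for i, tile in enumerate(level1):
        for q, sub in enumerate(_quarter(tile)):
            regions.append(Region(sub, level=2, tile_index=4 * i + q, sample_id=sid))
    return PyramidSet(regions=regions, sample_id=sid)


def spp_concat(
    vectors: list[np.ndarray], names: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Concatenate the 21 per-region feature vectors into one 1155-vector.

    Parameters
    ----------
    vectors : list of 21 arrays of length 55, in PyramidSet order.
    names : optional list of the 55 feature names; defaults to the
        canonical schema.

    Returns
    -------
    (values, names) where names carry a ``_L{level}T{tile}`` suffix.
    """
    from sppe.features import FEATURE_NAMES, N_FEATURES

    if names is None:
        names = FEATURE_NAMES
    if len(vectors) != N_REGIONS:
        raise ValueError(f"expected {N_REGIONS} vectors, got {len(vectors)}")
    arrs = []
    for k, v in enumerate(vectors):
        v = np.asarray(v, dtype=np.float64).ravel()
        if v.size != N_FEATURES:
            raise ValueError(f"vector {k} has length {v.size}, expected {N_FEATURES}")
        arrs.append(v)
    out_names: list[str] = []
    k = 0
    for level in (0, 1, 2):
        for tile in range(LEVEL_SIZES[level]):
            out_names.extend(f"{nm}_L{level}T{tile}" for nm in names)
            k += 1
    return np.concatenate(arrs), out_names
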