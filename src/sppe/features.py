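"""The 55-feature descriptor: 30 color, 6 intensity, 19 texture features.

Conventions (fixed for reproducibility; documented because several are
underdetermined by name alone):

* Intensity is the per-pixel mean of R, G, B, in [0, 255].
* HSV channels are in [0, 1]; L* in [0, 100]; a*, b* on their native
  signed scale (sRGB input, D65 illuminant, 2 degree observer).
* "Histogram" statistics (stdHist*, kurtHist*, skewHist*) are moments of
  the 256-element bin-count sequence of the channel histogram — a shape
  summary of the histogram itself, distinct from the pixel-level mean/std.
* All entropies are in bits (log base 2), with 0 * log 0 = 0.
* Skewness is moment-based; kurtosis is excess kurtosis (normal -> 0).
* GLCM: offset distance 1, angle 0 (horizontal neighbor), 256 grey
  levels, symmetric accumulation, normalized to sum 1.
* FFT statistics treat the normalized squared-magnitude spectrum (DC bin
  excluded) as a probability distribution; the radial distance of a bin
  from the zero-frequency origin plays the role the grey-level difference
  |i - j| plays for the GLCM.  A constant region has an empty spectrum
  and all four FFT features are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import color as skcolor
from skimage.feature import graycomatrix, local_binary_pattern

from sppe.preprocess import to_monochrome
from sppe.pyramid import Region

N_FEATURES = 55
N_COLOR = 30
N_INTENSITY = 6
N_LBP = 10
N_GLCM = 5
N_FFT = 4

_HIST_STATS = ("stdHist", "kurtHist", "skewHist")

COLOR_FEATURE_NAMES = [
    "meanH", "StdH", "meanS", "stdS", "MeanV", "stdV",
    "stdHistH", "kurtHistH", "skewHistH",
    "stdHistS", "kurtHistS", "skewHistS",
    "stdHistV", "kurtHistV", "skewHistV",
    "meanL", "stdL", "meanA", "stdA", "meanB", "stdB",
    "stdHistL", "kurtHistL", "skewHistL",
    "stdHistA", "kurtHistA", "skewHistA",
    "stdHistB", "kurtHistB", "skewHistB",
]
INTENSITY_FEATURE_NAMES = [
    "meanInten", "StdInten", "entropyInten",
    "stdHistInten", "kurtHistInten", "skewHistInten",
]
LBP_FEATURE_NAMES = [f"lbp_{i}" for i in range(N_LBP)]
GLCM_FEATURE_NAMES = [
    "entCoMatrix", "ineCoMatrix", "eneCoMatrix", "corCoMatrix", "homCoMatrix",
]
FFT_FEATURE_NAMES = ["eneFFT", "entFFT", "ineFFT", "homFFT"]

#: Canonical order of the 55 descriptor names.
FEATURE_NAMES: list[str] = (
    COLOR_FEATURE_NAMES
    + INTENSITY_FEATURE_NAMES
    + LBP_FEATURE_NAMES
    + GLCM_FEATURE_NAMES
    + FFT_FEATURE_NAMES
)

#: Histogram range per color channel, fixed so bins are comparable
#: across regions.
_CHANNEL_RANGES = {
    "H": (0.0, 1.0),
    "S": (0.0, 1.0),
    "V": (0.0, 1.0),
    "L": (0.0, 100.0),
    "A": (-128.0, 128.0),
    "B": (-128.0, 128.0),
}


@dataclass
class FeatureVector:
    """A 55-long named descriptor with region provenance."""

    values: np.ndarray
    sample_id: str = ""
    level: int = 0
    tile_index: int = 0
    label: str = "unknown"
    names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if v.size != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} values, got {v.size}")
        if not np.all(np.isfinite(v)):
            bad = [self.names[i] for i in np.flatnonzero(~np.isfinite(v))]
            raise ValueError(f"non-finite features {bad} in {self.sample_id!r}")
        self.values = v

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def _pixels(region: Region | np.ndarray) -> np.ndarray:
    return region.pixels if isinstance(region, Region) else np.asarray(region)


def _hist_moments(counts: np.ndarray) -> tuple[float, float, float]:
    """std / excess kurtosis / skewness of a bin-count sequence.

    Degenerate (constant) count sequences return 0 for kurtosis and
    skewness so the feature vector stays finite.
    """
    counts = counts.astype(np.float64)
    sd = float(counts.std())
    if sd == 0.0:
        return 0.0, 0.0, 0.0
    kurt = float(stats.kurtosis(counts, fisher=True, bias=True))
    skew = float(stats.skew(counts, bias=True))
    return sd, kurt, skew


def _channel_stats(channel: np.ndarray, rng: tuple[float, float]) -> dict[str, float]:
    flat = channel.ravel().astype(np.float64)
    counts, _ = np.histogram(flat, bins=256, range=rng)
    sd_h, kurt_h, skew_h = _hist_moments(counts)
    return {
        "mean": float(flat.mean()),
        "std": float(flat.std()),
        "stdHist": sd_h,
        "kurtHist": kurt_h,
        "skewHist": skew_h,
    }


def color_features(region: Region | np.ndarray) -> np.ndarray:
    """The 30 color features: HSV and L*a*b* moments + histogram statistics."""
    px = _pixels(region)
    if px.shape[0] * px.shape[1] < 4:
        raise ValueError("region too small for color features (< 4 pixels)")
    rgb = px.astype(np.float64) / 255.0
    hsv = skcolor.rgb2hsv(rgb)
    lab = skcolor.rgb2lab(rgb)
    channels = {
        "H": hsv[..., 0], "S": hsv[..., 1], "V": hsv[..., 2],
        "L": lab[..., 0], "A": lab[..., 1], "B": lab[..., 2],
    }
    st = {k: _channel_stats(v, _CHANNEL_RANGES[k]) for k, v in channels.items()}
    out = [
        st["H"]["mean"], st["H"]["std"],
        st["S"]["mean"], st["S"]["std"],
        st["V"]["mean"], st["V"]["std"],
    ]
    for ch in ("H", "S", "V"):
        out.extend(st[ch][k] for k in _HIST_STATS)
    for ch in ("L", "A", "B"):
        out.extend([st[ch]["mean"], st[ch]["std"]])
    for ch in ("L", "A", "B"):
        out.extend(st[ch][k] for k in _HIST_STATS)
    return np.asarray(out, dtype=np.float64)


def intensity_features(region: Region | np.ndarray) -> np.ndarray:
    """Mean, std, histogram entropy (bits) and histogram shape moments."""
    px = _pixels(region)
    if px.shape[0] * px.shape[1] < 4:
        raise ValueError("region too small for intensity features (< 4 pixels)")
    inten = to_monochrome(px).ravel()
    counts, _ = np.histogram(inten, bins=256, range=(0.0, 256.0))
    p = counts / counts.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    sd_h, kurt_h, skew_h = _hist_moments(counts)
    return np.asarray(
        [float(inten.mean()), float(inten.std()), entropy, sd_h, kurt_h, skew_h],
        dtype=np.float64,
    )


def lbp_features(region: Region | np.ndarray) -> np.ndarray:
    """Normalized 10-bin rotation-invariant uniform LBP histogram (P=8, R=1)."""
    px = _pixels(region)
    if min(px.shape[0], px.shape[1]) < 3:
        raise ValueError("region side must be >= 3 for LBP")
    # channel sum = 3 * intensity: same ordering, integer dtype (avoids the
    # float-comparison instability local_binary_pattern warns about)
    inten3 = px.astype(np.int64).sum(axis=2)
    codes = local_binary_pattern(inten3, P=8, R=1, method="uniform")
    interior = codes[1:-1, 1:-1]  # full 8-neighborhood exists only here
    counts, _ = np.histogram(interior, bins=N_LBP, range=(0, N_LBP))
    return counts / counts.sum()


def glcm_matrix(region: Region | np.ndarray) -> np.ndarray:
    """Symmetric normalized 256-level co-occurrence matrix, offset (0, +1)."""
    px = _pixels(region)
    if px.shape[1] < 2:
        raise ValueError("region must have >= 2 columns for the GLCM")
    inten = np.clip(np.round(to_monochrome(px)), 0, 255).astype(np.uint8)
    m = graycomatrix(
        inten, distances=[1], angles=[0.0], levels=256, symmetric=True, normed=True
    )
    return m[:, :, 0, 0]


def glcm_features(region: Region | np.ndarray) -> np.ndarray:
    """Entropy, inertia, energy, correlation and homogeneity of the GLCM."""
    p = glcm_matrix(region)
    i, j = np.indices(p.shape)
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    inertia = float(((i - j) ** 2 * p).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 1.0  # degenerate single-level region
    else:
        correlation = float(
            (((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j)
        )
    return np.asarray(
        [entropy, inertia, energy, correlation, homogeneity], dtype=np.float64
    )


def fft_spectrum(region: Region | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized power spectrum (DC excluded) and squared radial distances.

    Returns ``(P, d2)`` where ``P`` sums to 1 unless the region is constant,
    in which case ``P`` is all-zero.
    """
    px = _pixels(region)
    if min(px.shape[0], px.shape[1]) < 2:
        raise ValueError("region side must be >= 2 for FFT features")
    inten = to_monochrome(px)
    f = np.fft.fftshift(np.fft.fft2(inten - inten.mean()))
    power = np.abs(f) ** 2
    h, w = power.shape
    cr, cc = h // 2, w // 2  # DC position after fftshift
    power[cr, cc] = 0.0
    rr, cc_idx = np.indices(power.shape)
    d2 = (rr - cr) ** 2.0 + (cc_idx - cc) ** 2.0
    total = power.sum()
    if total <= 1e-12 * inten.size:
        return np.zeros_like(power), d2
    return power / total, d2


def fft_features(region: Region | np.ndarray) -> np.ndarray:
    """Energy, entropy, inertia and homogeneity of the power spectrum."""
    p, d2 = fft_spectrum(region)
    if p.sum() == 0.0:  # constant region: empty spectrum
        return np.zeros(N_FFT, dtype=np.float64)
    nz = p[p > 0]
    energy = float((p**2).sum())
    entropy = float(-(nz * np.log2(nz)).sum())
    inertia = float((d2 * p).sum())
    homogeneity = float((p / (1.0 + d2)).sum())
    return np.asarray([energy, entropy, inertia, homogeneity], dtype=np.float64)


def extract_all(region: Region, label: str = "unknown") -> FeatureVector:
    """Compute the full 55-feature descriptor of a region."""
    values = np.concatenate(
        [
            color_features(region),
            intensity_features(region),
            lbp_features(region),
            glcm_features(region),
            fft_features(region),
        ]
    )
    return FeatureVector(
        values=values,
        sample_id=region.sample_id,
        level=region.level,
        tile_index=region.tile_index,
        label=label,
    )
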