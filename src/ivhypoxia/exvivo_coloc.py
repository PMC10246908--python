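"""Serial-section colocalization: coarse downsampling, pairwise Pearson
matrices among stains, and top-decile positive-stain fractions within
viable tumor tissue.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .roi_vasculature import RegionMask
from .stats_report import pearson


@dataclass
class StainSet:
    """Registered single-stain images sharing one pixel grid."""

    stains: dict[str, np.ndarray]
    pixel_size_um: float
    registered: bool = True

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(img).shape for name, img in self.stains.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"stain images differ in shape: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def names(self) -> list[str]:
        return list(self.stains)


@dataclass
class ColocResult:
    """Symmetric pairwise Pearson matrix over stains."""

    r: pd.DataFrame
    n_pixels_used: int


def coarse_downsample(image: np.ndarray, factor: int = 100) -> np.ndarray:
    """Shrink each axis by `factor` with bicubic interpolation.

    Output dimensions are ceil(input / factor); bicubic overshoot below
    zero is clipped back to 0.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    image = np.asarray(image, dtype=float)
    if factor == 1:
        return image.copy()
    out_shape = tuple(int(np.ceil(s / factor)) for s in image.shape)
    out = resize(image, out_shape, order=3, anti_aliasing=True, mode="reflect")
    return np.clip(out, 0.0, None)


def tissue_mask(stains: StainSet) -> np.ndarray:
    """Union of per-stain Otsu foregrounds — pixels carrying any tissue."""
    mask = np.zeros(next(iter(stains.stains.values())).shape, bool)
    for img in stains.stains.values():
        img = np.asarray(img, dtype=float)
        if np.ptp(img) == 0:
            continue
        mask |= img > threshold_otsu(img)
    return mask


def coloc_matrix(
    stains: StainSet,
    pairs: list[tuple[str, str]] | None = None,
    mask: np.ndarray | str | None = "tissue",
) -> ColocResult:
    """Pairwise Pearson coefficients between stain intensity images.

    Parameters
    ----------
    stains : StainSet
        Must be registered (and normally already coarse-downsampled).
    pairs : list of (name, name), optional
        Defaults to all unordered pairs.
    mask : ndarray, "tissue", or None
        Pixels included in the correlation; "tissue" (default) uses the
        union of per-stain Otsu foregrounds, None uses every pixel.

    Constant stains yield NaN entries (undefined correlation) with a
    warning rather than an error.
    """
    if not stains.registered:
        raise ValueError("stain set must be registered")
    names = stains.names
    if pairs is None:
        pairs = list(itertools.combinations(names, 2))
    if isinstance(mask, str) and mask == "tissue":
        mask = tissue_mask(stains)
    if mask is None:
        mask = np.ones(next(iter(stains.stains.values())).shape, bool)

    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    n_used = int(mask.sum())
    for a, b in pairs:
        xa = np.asarray(stains.stains[a], float)[mask]
        xb = np.asarray(stains.stains[b], float)[mask]
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            warnings.warn(
                f"constant stain in pair ({a}, {b}): r undefined", stacklevel=2
            )
            val = np.nan
        else:
            val = pearson(xa, xb).r
        r.loc[a, b] = r.loc[b, a] = val
    return ColocResult(r=r, n_pixels_used=n_used)


def positive_stain_fraction(
    stain: np.ndarray,
    viable: RegionMask,
    pooled_values: np.ndarray,
    percentile: float = 90.0,
) -> float:
    """Fraction of viable-tumor pixels above the pooled top-decile cut.

    The threshold is the given percentile of `pooled_values` (stain
    intensities pooled across all tumors for that stain); the fraction
    is the count of viable-mask pixels at or above it over the viable
    pixel count.
    """
    if viable.is_empty:
        raise ValueError("viable-tumor mask is empty")
    stain = np.asarray(stain, dtype=float)
    if stain.shape != viable.mask.shape:
        raise ValueError("stain and mask shapes differ")
    threshold = float(np.percentile(np.asarray(pooled_values, float), percentile))
    vals = stain[viable.mask]
    return float(np.mean(vals >= threshold))


def in_vivo_vs_ex_vivo(
    in_vivo_mean_gfp: np.ndarray,
    ex_vivo_fraction: np.ndarray,
    exclude_zero_fraction: bool = True,
):
    """Correlate per-tumor in vivo reporter intensity with ex vivo stain fraction.

    Tumors whose ex vivo positive fraction is exactly 0 (no positive
    staining) are excluded by default before correlating.

    Returns
    -------
    CorrelationResult
    """
    x = np.asarray(in_vivo_mean_gfp, dtype=float)
    y = np.asarray(ex_vivo_fraction, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if exclude_zero_fraction:
        keep = y > 0
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 tumors after exclusions")
    return pearson(x, y)
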