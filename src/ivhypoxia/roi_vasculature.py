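"""Tumor-ROI segmentation, vessel segmentation, and hypoxia-gradient sampling.

Implements the in vivo quantification chain: threshold the tumor-cell
channel into a binary ROI, dilate it by a physical distance to capture
peritumoral vessels, segment vessels by superpixel clustering plus
adaptive thresholding, and sample reporter intensity on a physical grid
against the Euclidean distance to the nearest vessel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_local, threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.segmentation import slic

MaskKind = Literal["tumor_roi", "expanded_tumor_roi", "vessel", "viable_tumor"]


def dilate_by_distance(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Euclidean dilation: pixels within `radius_px` of the mask.

    Equivalent to binary dilation with a Euclidean disk footprint but
    computed through the exact distance transform, which stays cheap
    for large radii.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius_px <= 0 or not mask.any():
        return mask.copy()
    return ndimage.distance_transform_edt(~mask) <= radius_px

#: Threshold specification: a fixed value, "otsu" (Otsu on log intensity),
#: or ("percentile", q) — the q-th percentile of the image (or of a
#: background region when one is supplied to the segmenting function).
ThresholdSpec = float | str | tuple


@dataclass
class RegionMask:
    """Binary 2D mask with physical pixel size and provenance kind."""

    mask: np.ndarray
    pixel_size_um: float
    kind: MaskKind
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()


@dataclass
class RoiMetrics:
    """Per-image summary metrics over the tumor / expanded ROIs."""

    gfp_positive_fraction: float
    mean_gfp_intensity: float
    vascular_density: float
    n_tumor_pixels: int

    def to_dict(self) -> dict:
        return {
            "gfp_positive_fraction": self.gfp_positive_fraction,
            "mean_gfp_intensity": self.mean_gfp_intensity,
            "vascular_density": self.vascular_density,
            "n_tumor_pixels": self.n_tumor_pixels,
        }


@dataclass
class CellSample:
    """One grid-sampled tumor-cell record."""

    x_px: int
    y_px: int
    gfp_intensity: float
    distance_um: float
    gfp_level: str | None = None


def cells_to_frame(cells: Sequence[CellSample]) -> pd.DataFrame:
    """Convert a list of cell samples to the canonical CSV table layout."""
    return pd.DataFrame(
        {
            "x_px": [c.x_px for c in cells],
            "y_px": [c.y_px for c in cells],
            "gfp_intensity": [c.gfp_intensity for c in cells],
            "distance_um": [c.distance_um for c in cells],
            "gfp_level": [c.gfp_level for c in cells],
        }
    )


def resolve_threshold(
    image: np.ndarray,
    spec: ThresholdSpec,
    background: np.ndarray | None = None,
) -> float:
    """Turn a threshold specification into a concrete intensity value."""
    if isinstance(spec, (int, float)) and not isinstance(spec, bool):
        return float(spec)
    if spec == "otsu":
        vals = np.log1p(np.asarray(image, dtype=float))
        if np.ptp(vals) == 0:
            return float(np.expm1(vals.flat[0]))
        return float(np.expm1(threshold_otsu(vals)))
    if isinstance(spec, tuple) and len(spec) == 2 and spec[0] == "percentile":
        source = background if background is not None else image
        return float(np.percentile(source, spec[1]))
    raise ValueError(f"unrecognized threshold spec: {spec!r}")


def segment_tumor_roi(
    dsred: np.ndarray,
    threshold_spec: ThresholdSpec = "otsu",
    pixel_size_um: float = 1.0,
    min_area_px: int = 50,
    background: np.ndarray | None = None,
) -> RegionMask:
    """Threshold the tumor-cell channel into a binary tumor ROI.

    Pixels strictly above the resolved threshold are kept, then
    connected components smaller than `min_area_px` are removed. An
    empty result is returned flagged (with a warning) rather than
    raising.
    """
    dsred = np.asarray(dsred, dtype=float)
    if dsred.size == 0:
        raise ValueError("empty image")
    thr = resolve_threshold(dsred, threshold_spec, background)
    mask = dsred > thr
    if min_area_px > 1:
        mask = remove_small_objects(mask, max_size=min_area_px - 1)
    flags = []
    if not mask.any():
        warnings.warn("tumor segmentation produced an empty mask", stacklevel=2)
        flags.append("empty_mask")
    return RegionMask(mask, pixel_size_um, "tumor_roi", flags)


def gfp_metrics(
    gfp: np.ndarray, tumor: RegionMask, gfp_threshold: float
) -> RoiMetrics:
    """GFP-positive fraction and mean GFP intensity over the tumor ROI.

    The positive fraction is the number of tumor-ROI pixels whose GFP
    intensity exceeds `gfp_threshold`, divided by the ROI pixel count;
    the mean is the plain average over the ROI.
    """
    gfp = np.asarray(gfp, dtype=float)
    if gfp.shape != tumor.mask.shape:
        raise ValueError("image and mask shapes differ")
    if tumor.is_empty:
        raise ValueError("tumor mask is empty")
    vals = gfp[tumor.mask]
    return RoiMetrics(
        gfp_positive_fraction=float(np.mean(vals > gfp_threshold)),
        mean_gfp_intensity=float(vals.mean()),
        vascular_density=float("nan"),
        n_tumor_pixels=int(vals.size),
    )


def expand_roi(tumor: RegionMask, distance_um: float = 100.0) -> RegionMask:
    """Morphologically dilate the tumor ROI by a physical distance.

    Dilation uses a Euclidean disk of radius round(distance_um /
    pixel_size_um) pixels; the output is always a superset of the
    input.
    """
    if distance_um < 0:
        raise ValueError("distance_um must be non-negative")
    radius_px = int(round(distance_um / tumor.pixel_size_um))
    expanded = dilate_by_distance(tumor.mask, radius_px)
    return RegionMask(expanded, tumor.pixel_size_um, "expanded_tumor_roi")


def segment_vessels(
    apc: np.ndarray,
    n_superpixels: int | None = None,
    compactness: float = 0.1,
    adaptive_window_px: int = 51,
    offset: float = 0.0,
    pixel_size_um: float = 1.0,
    background_percentile: float = 50.0,
) -> RegionMask:
    """Segment vessels: SLIC superpixels followed by adaptive thresholding.

    Superpixels are computed on the vessel-marker channel alone; each
    superpixel is replaced by its mean intensity, and that piecewise-
    constant image is thresholded with a local sliding-window mean
    (minus `offset`).

    Parameters
    ----------
    apc : 2D array
        Vessel-marker intensity image.
    n_superpixels : int, optional
        Defaults to ``image_area / 256``.
    compactness : float
        SLIC compactness for intensity-only clustering.
    adaptive_window_px : int
        Side of the local-mean window; must be odd and fit in the image.
    offset : float
        Subtracted from the local mean before comparison.
    background_percentile : float
        Pixels at or below this global intensity percentile are removed
        from the final mask (trims superpixel overhang past the vessel
        wall).
    """
    apc = np.asarray(apc, dtype=float)
    if adaptive_window_px > min(apc.shape):
        raise ValueError(
            f"adaptive window ({adaptive_window_px} px) larger than image "
            f"{apc.shape}"
        )
    if np.ptp(apc) == 0:
        # Constant image carries no vessel signal.
        return RegionMask(np.zeros_like(apc, bool), pixel_size_um, "vessel")
    if n_superpixels is None:
        n_superpixels = max(16, apc.size // 256)
    labels = slic(
        apc,
        n_segments=n_superpixels,
        compactness=compactness,
        channel_axis=None,
        start_label=0,
        enforce_connectivity=True,
    )
    means = ndimage.mean(apc, labels=labels, index=np.arange(labels.max() + 1))
    mean_img = means[labels]
    block = adaptive_window_px if adaptive_window_px % 2 == 1 else adaptive_window_px + 1
    local = threshold_local(mean_img, block_size=block, method="mean", offset=offset)
    # Ties (flat regions) are background; the tolerance absorbs the
    # sliding-window mean's floating-point jitter around zero.
    mask = (mean_img - local) > 1e-9 * np.ptp(apc)
    # Trim superpixel overhang: keep only pixels above global background.
    mask &= apc > np.percentile(apc, background_percentile)
    return RegionMask(mask, pixel_size_um, "vessel")


def vascular_density(vessels: RegionMask, expanded: RegionMask) -> float:
    """Fraction of expanded-ROI pixels segmented as vessel."""
    if vessels.mask.shape != expanded.mask.shape:
        raise ValueError("mask shapes differ")
    n_roi = expanded.n_pixels
    if n_roi == 0:
        raise ValueError("expanded ROI is empty")
    return float(np.logical_and(vessels.mask, expanded.mask).sum() / n_roi)


def vessel_distance_map(vessels: RegionMask) -> np.ndarray:
    """Euclidean distance (um) from every pixel to the nearest vessel pixel.

    Exact distance transform of the vessel-mask complement scaled by
    the pixel size; 0 on vessel pixels. An empty vessel mask yields an
    all-infinity map with a warning.
    """
    if vessels.is_empty:
        warnings.warn("vessel mask is empty: distance map is infinite", stacklevel=2)
        return np.full(vessels.mask.shape, np.inf)
    return ndimage.distance_transform_edt(~vessels.mask) * vessels.pixel_size_um


def sample_cells(
    tumor: RegionMask,
    gfp: np.ndarray,
    dmap: np.ndarray,
    spacing_um: float = 20.0,
) -> list[CellSample]:
    """Sample cell-sized grid points inside the tumor ROI.

    A regular grid with pitch round(spacing_um / pixel_size_um) pixels,
    anchored at the image origin, is intersected with the tumor mask;
    each retained point records the reporter intensity and the vessel
    distance at that pixel.
    """
    pitch = int(round(spacing_um / tumor.pixel_size_um))
    if pitch < 1:
        raise ValueError("spacing must be at least one pixel")
    gfp = np.asarray(gfp, dtype=float)
    dmap = np.asarray(dmap, dtype=float)
    if gfp.shape != tumor.mask.shape or dmap.shape != tumor.mask.shape:
        raise ValueError("image/mask/distance shapes differ")
    h, w = tumor.mask.shape
    rows = np.arange(0, h, pitch)
    cols = np.arange(0, w, pitch)
    cells: list[CellSample] = []
    for y in rows:
        inside = tumor.mask[y, cols]
        for x in cols[inside]:
            cells.append(
                CellSample(
                    x_px=int(x),
                    y_px=int(y),
                    gfp_intensity=float(gfp[y, x]),
                    distance_um=float(dmap[y, x]),
                )
            )
    return cells


def bivariate_histogram(
    cells: Sequence[CellSample],
    distance_edges: np.ndarray,
    intensity_edges: np.ndarray,
) -> np.ndarray:
    """2D probability histogram of (distance, intensity) over cell samples.

    Counts are normalized so the whole array sums to 1. Samples outside
    the bin ranges are dropped before normalization.
    """
    if len(cells) == 0:
        raise ValueError("no cell samples")
    d = np.array([c.distance_um for c in cells])
    i = np.array([c.gfp_intensity for c in cells])
    counts, _, _ = np.histogram2d(d, i, bins=[distance_edges, intensity_edges])
    total = counts.sum()
    if total == 0:
        raise ValueError("all samples fall outside the histogram edges")
    return counts / total


def classify_gfp_levels(
    cells: Sequence[CellSample], low_cut: float, high_cut: float
) -> list[CellSample]:
    """Assign low/moderate/high reporter levels with half-open bins.

    low = [0, low_cut), moderate = [low_cut, high_cut),
    high = [high_cut, inf). Returns new records; input is not mutated.
    """
    if low_cut > high_cut:
        raise ValueError("low_cut must not exceed high_cut")
    out = []
    for c in cells:
        if c.gfp_intensity < low_cut:
            level = "low"
        elif c.gfp_intensity < high_cut:
            level = "moderate"
        else:
            level = "high"
        out.append(
            CellSample(c.x_px, c.y_px, c.gfp_intensity, c.distance_um, level)
        )
    return out
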