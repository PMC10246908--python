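"""Peritumoral collagen analysis: interface tracing, moving ROIs, and
FFT-based fiber orientation with the ellipse alignment score.

Orientation pipeline: a mean-subtracted, radially windowed patch is
Fourier transformed; the central circular region of the power spectrum
is summed into 1-degree angular bins; the binned polar distribution is
fit with an ellipse via second central moments. The ellipse tilt
(rotated 90 degrees, spectrum being perpendicular to spatial structure)
gives the dominant fiber direction and the axis ratio gives the
alignment score (1 - b/a) * 100.

Angles are reported in [0, 180) degrees with 0 along the +x (column)
axis, measured counterclockwise with y pointing up; relative
orientations are folded to [0, 90].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.draw import line_aa

from .roi_vasculature import RegionMask
from .spectral import SpectralImage


@dataclass
class FiberStats:
    """Dominant orientation and ellipse-based alignment of a patch."""

    orientation_deg: float
    a: float
    b: float
    alignment_score: float
    relative_orientation_deg: float = float("nan")
    valid: bool = True


@dataclass
class InterfaceLine:
    """Ordered polyline along the tumor-collagen interface.

    Vertices are (row, col) pixel coordinates (sub-pixel, from contour
    tracing); `closed` marks a loop whose last vertex joins the first.
    """

    vertices: np.ndarray
    pixel_size_um: float
    closed: bool

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (row, col)")

    @property
    def arc_length_um(self) -> float:
        pts = self.vertices
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        seg = np.diff(pts, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum() * self.pixel_size_um)


@dataclass
class PeritumoralRoi:
    """One 100-um moving-window record along the interface."""

    center: tuple[float, float]  # (row, col) px
    diameter_um: float
    mean_gfp: float
    mean_shg: float
    fiber: FiberStats
    flags: list[str] = field(default_factory=list)


def alignment_score(a: float, b: float) -> float:
    """Alignment score (1 - b/a) * 100 from ellipse semi-axes.

    0 for an isotropic (circular) fit, 100 for a degenerate fully
    aligned fit (b = 0).
    """
    if a <= 0:
        raise ValueError("major semi-axis a must be positive")
    if b < 0 or b > a:
        raise ValueError("minor semi-axis b must satisfy 0 <= b <= a")
    return (1.0 - b / a) * 100.0


def relative_orientation(fiber_deg: float, edge_deg: float) -> float:
    """Acute angle between two axial orientations, in [0, 90] degrees."""
    delta = abs(fiber_deg - edge_deg) % 180.0
    return min(delta, 180.0 - delta)


def ellipse_from_polar(power: np.ndarray, bin_deg: float = 1.0):
    """Fit an ellipse to an angular power distribution by second moments.

    The binned distribution (power per angle over [0, 180)) is treated
    as a point cloud: one point per bin at radius = power, mirrored to
    [0, 360) by the spectrum's point symmetry. Second central moments
    of the cloud give the ellipse semi-axes and tilt.

    Returns
    -------
    (a, b, tilt_deg) : semi-major axis, semi-minor axis, major-axis
    angle in [0, 180) degrees.
    """
    power = np.asarray(power, dtype=float)
    if power.ndim != 1 or power.size == 0:
        raise ValueError("power must be a non-empty 1D array")
    if np.any(power < 0):
        raise ValueError("power must be non-negative")
    theta = np.deg2rad(np.arange(power.size) * bin_deg)
    x = power * np.cos(theta)
    y = power * np.sin(theta)
    # Mirror points: cloud is centrally symmetric, centroid at origin.
    xx = np.mean(x * x)
    yy = np.mean(y * y)
    xy = np.mean(x * y)
    cov = np.array([[xx, xy], [xy, yy]])
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    # A degenerate (single-angle) cloud is analytically rank 1 and an
    # isotropic one has exactly equal moments; in both cases the
    # eigenvalue gap below machine precision is floating-point residue.
    if evals[1] > 0:
        evals[evals < evals[1] * 1e-12] = 0.0
        if evals[1] - evals[0] < evals[1] * 1e-12:
            evals[0] = evals[1]
    a = float(np.sqrt(evals[1]))
    b = float(np.sqrt(evals[0]))
    major = evecs[:, 1]
    tilt = float(np.rad2deg(np.arctan2(major[1], major[0])) % 180.0)
    return a, b, tilt


def polar_power_spectrum(patch: np.ndarray, bin_deg: float = 1.0) -> np.ndarray:
    """Angular power distribution of a square patch over [0, 180).

    The patch is mean-subtracted, radially Hann-windowed, Fourier
    transformed; the power spectrum (DC zeroed) is restricted to the
    central circle and summed into angular bins. The angle of each
    frequency sample is measured with y up, matching the spatial
    orientation convention.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError("patch must be square")
    n = patch.shape[0]
    if n < 32:
        raise ValueError("patch side must be at least 32 px")

    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    rmax = n / 2.0
    window = np.where(r <= rmax, 0.5 * (1 + np.cos(np.pi * r / rmax)), 0.0)
    windowed = (patch - patch.mean()) * window

    spec = np.fft.fftshift(np.fft.fft2(windowed))
    power = np.abs(spec) ** 2
    v = np.fft.fftshift(np.fft.fftfreq(n))  # row (y) frequency
    u = v.copy()  # square patch: same grid along columns
    vv, uu = np.meshgrid(v, u, indexing="ij")
    rho = np.hypot(vv, uu)
    power[rho == 0] = 0.0  # zero the DC bin
    circle = rho <= 0.5  # radius = min dimension / 2 in frequency px

    # y axis of the image points down; negate the row frequency so that
    # spectral angles share the y-up spatial convention.
    ang = np.rad2deg(np.arctan2(-vv, uu)) % 180.0
    nbins = int(round(180.0 / bin_deg))
    idx = np.minimum((ang[circle] / bin_deg).astype(int), nbins - 1)
    return np.bincount(idx, weights=power[circle], minlength=nbins)


def fiber_orientation(patch: np.ndarray, bin_deg: float = 1.0) -> FiberStats:
    """Dominant fiber orientation and alignment score of a square patch.

    A constant (or signal-free) patch has no defined orientation: the
    result is flagged invalid with alignment score 0.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError("patch must be square")
    if patch.shape[0] < 32:
        raise ValueError("patch side must be at least 32 px")
    if np.ptp(patch) == 0:
        return FiberStats(float("nan"), 0.0, 0.0, 0.0, valid=False)
    power = polar_power_spectrum(patch, bin_deg)
    total = power.sum()
    if total <= 0:
        return FiberStats(float("nan"), 0.0, 0.0, 0.0, valid=False)
    a, b, tilt = ellipse_from_polar(power / total, bin_deg)
    if a <= 0:
        return FiberStats(float("nan"), 0.0, 0.0, 0.0, valid=False)
    # Spectral power concentrates perpendicular to the spatial fibers.
    orientation = (tilt + 90.0) % 180.0
    return FiberStats(orientation, a, b, alignment_score(a, b))


def _smooth_polyline(vertices: np.ndarray, closed: bool, window: int = 7) -> np.ndarray:
    """Moving-average smoothing of contour vertices.

    Marching-squares contours staircase along pixel edges, inflating
    arc length; a short moving average recovers the underlying smooth
    boundary without shifting it.
    """
    if len(vertices) <= window:
        return vertices
    mode = "wrap" if closed else "nearest"
    return ndimage.uniform_filter1d(vertices, size=window, axis=0, mode=mode)


def extract_interface(
    tumor: RegionMask,
    shg: np.ndarray,
    collagen_search_um: float = 20.0,
    shg_threshold: float | None = None,
) -> list[InterfaceLine]:
    """Trace tumor-boundary segments that face collagen signal.

    The outer contours of the tumor mask are traced; contour vertices
    with above-threshold collagen signal within `collagen_search_um`
    are retained and consecutive runs become ordered polylines. A fully
    retained loop stays closed.
    """
    if tumor.is_empty:
        raise ValueError("tumor mask is empty")
    shg = np.asarray(shg, dtype=float)
    if shg.shape != tumor.mask.shape:
        raise ValueError("image and mask shapes differ")
    if shg_threshold is None:
        shg_threshold = float(shg.max()) * 0.1
    contours = measure.find_contours(tumor.mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no tumor contour found")

    # Collagen within reach: dilate the above-threshold SHG support.
    collagen = shg > shg_threshold
    radius_px = max(1, int(round(collagen_search_um / tumor.pixel_size_um)))
    if collagen.any():
        near = ndimage.distance_transform_edt(~collagen) <= radius_px
    else:
        near = np.zeros_like(collagen)

    lines: list[InterfaceLine] = []
    h, w = tumor.mask.shape
    for contour in contours:
        rows = np.clip(np.round(contour[:, 0]).astype(int), 0, h - 1)
        cols = np.clip(np.round(contour[:, 1]).astype(int), 0, w - 1)
        keep = near[rows, cols]
        closed = bool(np.allclose(contour[0], contour[-1]))
        if closed:
            contour = contour[:-1]
            keep = keep[:-1]
        if keep.all() and closed:
            lines.append(
                InterfaceLine(
                    _smooth_polyline(contour, closed=True),
                    tumor.pixel_size_um,
                    closed=True,
                )
            )
            continue
        if not keep.any():
            continue
        # Split into consecutive runs; for a loop, rotate so a gap
        # starts the sequence, keeping runs contiguous across the seam.
        if closed:
            gap = int(np.argmin(keep))
            contour = np.roll(contour, -gap, axis=0)
            keep = np.roll(keep, -gap)
        edges = np.flatnonzero(np.diff(keep.astype(int)))
        starts = [i + 1 for i in edges if keep[i + 1]]
        ends = [i + 1 for i in edges if not keep[i + 1]]
        if keep[0]:
            starts = [0] + starts
        if keep[-1]:
            ends = ends + [len(keep)]
        for s, e in zip(starts, ends):
            if e - s >= 2:
                lines.append(
                    InterfaceLine(
                        _smooth_polyline(contour[s:e], closed=False),
                        tumor.pixel_size_um,
                        closed=False,
                    )
                )
    return lines


def place_rois(
    line: InterfaceLine,
    diameter_um: float = 100.0,
    spacing_um: float = 100.0,
) -> tuple[np.ndarray, list[str]]:
    """Centers of moving ROIs stepped along the interface by arc length.

    Centers sit at arc-length positions 0, spacing, 2*spacing, ...
    For closed lines the final center is dropped when it lies within
    spacing/2 of the first. A line shorter than one ROI diameter yields
    a single flagged center at its midpoint.

    Returns
    -------
    centers : (N, 2) array of (row, col) pixel coordinates
    flags : list of str ("short_line" when degenerate)
    """
    pts = line.vertices
    if line.closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1]) * line.pixel_size_um
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]

    def at(s: float) -> np.ndarray:
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(seg_len) - 1)
        t = 0.0 if seg_len[i] == 0 else (s - cum[i]) / seg_len[i]
        return pts[i] + t * (pts[i + 1] - pts[i])

    if total < diameter_um:
        return np.array([at(total / 2.0)]), ["short_line"]

    positions = np.arange(0.0, total + 1e-9, spacing_um)
    if line.closed and len(positions) > 1 and total - positions[-1] < spacing_um / 2:
        positions = positions[:-1]
    return np.array([at(s) for s in positions]), []


def edge_orientation(
    line: InterfaceLine,
    center: Sequence[float],
    window_um: float = 100.0,
) -> float:
    """Local orientation of the interface near a point, in [0, 180).

    The line segment within `window_um` of the center is rasterized
    into a patch and passed through the same FFT orientation pipeline
    used for fibers.
    """
    center = np.asarray(center, dtype=float)
    pts = line.vertices
    dist_um = np.hypot(*(pts - center).T) * line.pixel_size_um
    local = pts[dist_um <= window_um]
    if len(local) < 2:
        raise ValueError("fewer than 2 interface vertices inside the window")
    side = max(32, int(round(2 * window_um / line.pixel_size_um)))
    patch = np.zeros((side, side))
    offset = local - center + side / 2.0
    for p0, p1 in zip(offset[:-1], offset[1:]):
        rr, cc, val = line_aa(
            int(round(p0[0])), int(round(p0[1])), int(round(p1[0])), int(round(p1[1]))
        )
        ok = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
        patch[rr[ok], cc[ok]] = np.maximum(patch[rr[ok], cc[ok]], val[ok])
    stats = fiber_orientation(patch)
    if not stats.valid:
        raise ValueError("interface segment too short to orient")
    return stats.orientation_deg


def _disk_mask(shape: tuple[int, int], center: np.ndarray, radius_px: float):
    """Inclusive Euclidean disk (distance <= radius) clipped to the image.

    Returns the in-frame mask and the unclipped pixel count.
    """
    h, w = shape
    r_int = int(np.ceil(radius_px))
    r0, r1 = int(np.floor(center[0])) - r_int, int(np.ceil(center[0])) + r_int + 1
    c0, c1 = int(np.floor(center[1])) - r_int, int(np.ceil(center[1])) + r_int + 1
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2
    n_full = int(inside.sum())
    in_frame = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
    mask = np.zeros(shape, bool)
    sel = inside & in_frame
    mask[yy[sel], xx[sel]] = True
    return mask, n_full


def peritumoral_table(
    image: SpectralImage,
    tumor: RegionMask,
    centers: np.ndarray,
    line: InterfaceLine | None = None,
    diameter_um: float = 100.0,
    gfp_channel: str = "GFP",
    shg_channel: str = "SHG",
    edge_window_um: float = 100.0,
) -> list[PeritumoralRoi]:
    """Per-ROI means, fiber statistics, and edge-relative orientation.

    mean_gfp averages reporter intensity over disk-and-tumor overlap
    (undefined and flagged when the disk misses the tumor); mean_shg
    averages collagen signal over the whole in-frame disk. Disks
    clipped at the border are flagged when less than half remains.
    """
    gfp = image.channel(gfp_channel)
    shg = image.channel(shg_channel)
    px = image.pixel_size_um
    radius_px = diameter_um / 2.0 / px
    shape = gfp.shape
    side = max(32, int(round(diameter_um / px)))

    out: list[PeritumoralRoi] = []
    for center in np.atleast_2d(np.asarray(centers, dtype=float)):
        flags: list[str] = []
        dmask, n_full = _disk_mask(shape, center, radius_px)
        n_in = int(dmask.sum())
        if n_in == 0:
            continue
        if n_in < 0.5 * n_full:
            flags.append("clipped_disk")
        overlap = dmask & tumor.mask
        if overlap.any():
            mean_gfp = float(gfp[overlap].mean())
        else:
            mean_gfp = float("nan")
            flags.append("no_tumor_overlap")
        mean_shg = float(shg[dmask].mean())

        r0 = int(round(center[0] - side / 2))
        c0 = int(round(center[1] - side / 2))
        patch = np.zeros((side, side))
        rs, re = max(r0, 0), min(r0 + side, shape[0])
        cs, ce = max(c0, 0), min(c0 + side, shape[1])
        patch[rs - r0 : re - r0, cs - c0 : ce - c0] = shg[rs:re, cs:ce]
        fiber = fiber_orientation(patch)

        if line is not None and fiber.valid:
            try:
                edge = edge_orientation(line, center, edge_window_um)
                fiber.relative_orientation_deg = relative_orientation(
                    fiber.orientation_deg, edge
                )
            except ValueError:
                flags.append("no_edge_orientation")
        out.append(
            PeritumoralRoi(
                center=(float(center[0]), float(center[1])),
                diameter_um=diameter_um,
                mean_gfp=mean_gfp,
                mean_shg=mean_shg,
                fiber=fiber,
                flags=flags,
            )
        )
    return out


def rois_to_frame(rois: Sequence[PeritumoralRoi]) -> pd.DataFrame:
    """Convert peritumoral ROI records to the canonical CSV table."""
    return pd.DataFrame(
        {
            "center_y": [r.center[0] for r in rois],
            "center_x": [r.center[1] for r in rois],
            "mean_gfp": [r.mean_gfp for r in rois],
            "mean_shg": [r.mean_shg for r in rois],
            "orientation_deg": [r.fiber.orientation_deg for r in rois],
            "alignment_score": [r.fiber.alignment_score for r in rois],
            "relative_orientation_deg": [
                r.fiber.relative_orientation_deg for r in rois
            ],
            "flags": [";".join(r.flags) for r in rois],
        }
    )
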