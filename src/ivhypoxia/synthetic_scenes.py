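"""Synthetic intravital scenes, serial-section stain sets, and in vitro
time courses with known ground truth.

Scenes contain four fluorophore abundance maps — tumor cells, a
hypoxia reporter whose intensity rises with distance from vessels,
a vessel marker, and an oriented peritumoral fiber field — mixed into
detection channels through a known coefficient matrix and optionally
corrupted with shot and read noise. Every generator is a pure function
of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line_aa
from skimage.morphology import disk

from .roi_vasculature import RegionMask, dilate_by_distance
from .spectral import SpectralImage, UnmixMatrix, mix

FLUOROPHORES = ["DsRed", "GFP", "APC", "SHG"]

#: Sentinel distance for scenes without any vessel.
NO_VESSEL_DISTANCE = np.inf


@dataclass
class GfpGradient:
    """Saturating-exponential map from vessel distance (um) to intensity.

    intensity(d) = i_max * (1 - exp(-d / l_um)); l_um = 0 degenerates
    to a flat field at i_max (and the +inf "no vessel" sentinel always
    maps to the plateau i_max).
    """

    i_max: float
    l_um: float

    def __call__(self, distance_um: np.ndarray) -> np.ndarray:
        d = np.asarray(distance_um, dtype=float)
        if self.l_um <= 0:
            return np.full_like(d, self.i_max)
        out = self.i_max * (1.0 - np.exp(-d / self.l_um))
        return np.where(np.isinf(d), self.i_max, out)


@dataclass
class NoiseModel:
    """Poisson shot noise on scaled signal, then Gaussian read noise.

    Both default off so analytic round-trip tests stay exact.
    """

    gaussian_sigma: float = 0.0
    poisson_gain: float = 0.0

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(signal, dtype=float)
        if self.poisson_gain > 0:
            out = rng.poisson(np.clip(out, 0, None) * self.poisson_gain) / self.poisson_gain
        if self.gaussian_sigma > 0:
            out = out + rng.normal(0.0, self.gaussian_sigma, out.shape)
        return out


def identity_mixing_matrix() -> UnmixMatrix:
    """Identity coefficient matrix over the four standard fluorophores."""
    return UnmixMatrix(np.eye(4), list(FLUOROPHORES), list(FLUOROPHORES))


@dataclass
class SceneParams:
    """Everything needed to render one synthetic scene deterministically."""

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.186
    n_vessels: int = 3
    vessel_radius_um: float = 6.0
    tumor_radius_um: float = 180.0
    gfp_gradient: GfpGradient = field(default_factory=lambda: GfpGradient(100.0, 80.0))
    fiber_kappa: float = 8.0
    fiber_mean_angle_deg: float = 45.0
    mixing_matrix: UnmixMatrix = field(default_factory=identity_mixing_matrix)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    # Rendering knobs (levels in arbitrary intensity units)
    dsred_level: float = 100.0
    apc_level: float = 100.0
    shg_level: float = 80.0
    fiber_length_um: float = 30.0
    fiber_width_um: float = 2.0
    fiber_band_um: float = 120.0
    fiber_density_per_mm2: float = 3000.0
    tumor_boundary_wobble: float = 0.1

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.fiber_kappa < 0:
            raise ValueError("fiber_kappa must be non-negative")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be non-negative")
        m = self.mixing_matrix.values
        if m.shape[0] != len(FLUOROPHORES):
            raise ValueError(
                f"mixing matrix needs {len(FLUOROPHORES)} fluorophore rows"
            )
        if m.shape[0] == m.shape[1]:
            if abs(np.linalg.det(m)) < 1e-12:
                raise ValueError("mixing matrix is singular; unmixing impossible")
        elif m.shape[0] > m.shape[1]:
            raise ValueError("mixing matrix has more fluorophores than channels")


@dataclass
class GroundTruth:
    """Latent scene state the analysis pipeline is meant to recover."""

    tumor_mask: RegionMask
    vessel_mask: RegionMask
    true_distance_map: np.ndarray
    true_fiber_angle_deg: float
    true_abundances: dict[str, np.ndarray]


def _render_tumor(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    h, w = params.image_size_px
    cy, cx = h / 2.0, w / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx) * params.pixel_size_um
    theta = np.arctan2(yy - cy, xx - cx)
    # Low-order harmonic wobble keeps the boundary smooth but non-circular.
    radius = params.tumor_radius_um * (
        1.0
        + params.tumor_boundary_wobble
        * (
            rng.uniform(-1, 1) * np.cos(2 * theta + rng.uniform(0, 2 * np.pi))
            + rng.uniform(-1, 1) * np.cos(3 * theta + rng.uniform(0, 2 * np.pi))
        )
    )
    return r <= radius


def _render_vessels(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    h, w = params.image_size_px
    mask = np.zeros((h, w), bool)
    step_px = 3.0
    n_steps = int(1.2 * max(h, w) / step_px)
    for _ in range(params.n_vessels):
        pos = np.array([rng.uniform(0, h), rng.uniform(0, w)])
        heading = rng.uniform(0, 2 * np.pi)
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.25)
            nxt = pos + step_px * np.array([math.sin(heading), math.cos(heading)])
            rr, cc, _ = line_aa(
                int(round(pos[0])), int(round(pos[1])),
                int(round(nxt[0])), int(round(nxt[1])),
            )
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            mask[rr[ok], cc[ok]] = True
            pos = nxt
            if not (-h * 0.2 <= pos[0] <= h * 1.2 and -w * 0.2 <= pos[1] <= w * 1.2):
                break
    radius_px = max(1, int(round(params.vessel_radius_um / params.pixel_size_um)))
    return dilate_by_distance(mask, radius_px)


def _sample_fiber_angle(params: SceneParams, rng: np.random.Generator) -> float:
    """Axial angle in degrees: von Mises on the doubled angle."""
    if math.isinf(params.fiber_kappa):
        return params.fiber_mean_angle_deg % 180.0
    if params.fiber_kappa == 0:
        return float(rng.uniform(0.0, 180.0))
    mu = math.radians(2.0 * params.fiber_mean_angle_deg)
    sample = rng.vonmises(mu, params.fiber_kappa)
    return float(math.degrees(sample) / 2.0) % 180.0


def _render_fibers(
    params: SceneParams, tumor: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    h, w = params.image_size_px
    px = params.pixel_size_um
    band_px = max(1, int(round(params.fiber_band_um / px)))
    band = dilate_by_distance(tumor, band_px) & ~tumor
    field_img = np.zeros((h, w))
    coords = np.argwhere(band)
    if len(coords) == 0:
        return field_img
    area_mm2 = band.sum() * (px / 1000.0) ** 2
    n_fibers = max(1, int(round(params.fiber_density_per_mm2 * area_mm2)))
    half_len_px = params.fiber_length_um / 2.0 / px
    for _ in range(n_fibers):
        center = coords[rng.integers(len(coords))].astype(float)
        ang = math.radians(_sample_fiber_angle(params, rng))
        # y-up convention: row displacement is -sin(angle)
        d = np.array([-math.sin(ang), math.cos(ang)]) * half_len_px
        p0, p1 = center - d, center + d
        rr, cc, val = line_aa(
            int(round(p0[0])), int(round(p0[1])),
            int(round(p1[0])), int(round(p1[1])),
        )
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        np.maximum.at(field_img, (rr[ok], cc[ok]), val[ok])
    width_px = params.fiber_width_um / px
    if width_px > 1.5:
        field_img = ndimage.grey_dilation(
            field_img, footprint=disk(int(round(width_px / 2)))
        )
    return field_img * params.shg_level


def generate_scene(params: SceneParams) -> tuple[SpectralImage, GroundTruth]:
    """Render one scene and its ground truth.

    The four abundance maps (tumor marker, hypoxia reporter, vessel
    marker, fiber field) are mixed into channels via the coefficient
    matrix and then passed through the noise model. Identical params
    (including seed) give identical outputs.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size_px
    px = params.pixel_size_um

    tumor = _render_tumor(params, rng)
    vessels = _render_vessels(params, rng)
    if vessels.any():
        dmap = ndimage.distance_transform_edt(~vessels) * px
    else:
        dmap = np.full((h, w), NO_VESSEL_DISTANCE)

    abundances = {
        "DsRed": tumor.astype(float) * params.dsred_level,
        "GFP": np.where(tumor, params.gfp_gradient(dmap), 0.0),
        "APC": vessels.astype(float) * params.apc_level,
        "SHG": _render_fibers(params, tumor, rng),
    }
    a_stack = np.stack([abundances[f] for f in FLUOROPHORES])
    s_stack = mix(a_stack, params.mixing_matrix)
    s_stack = params.noise_model.apply(s_stack, rng)

    image = SpectralImage(s_stack, list(params.mixing_matrix.channel_names), px)
    truth = GroundTruth(
        tumor_mask=RegionMask(tumor, px, "tumor_roi"),
        vessel_mask=RegionMask(vessels, px, "vessel"),
        true_distance_map=dmap,
        true_fiber_angle_deg=params.fiber_mean_angle_deg % 180.0,
        true_abundances=abundances,
    )
    return image, truth


STAIN_NAMES = ["GFP", "PIMO", "CA9", "CD31", "DsRed"]

#: Default activation thresholds on the latent hypoxia field in [0, 1].
#: The exogenous low-oxygen marker switches on at a stricter (higher)
#: hypoxia level than the two transcription-driven stains, which share
#: a threshold family.
DEFAULT_STAIN_THRESHOLDS = {"GFP": 0.50, "CA9": 0.50, "PIMO": 0.65}


@dataclass
class SerialSections:
    """Five single-stain images sharing one latent hypoxia field."""

    stains: dict[str, np.ndarray]
    latent_hypoxia: np.ndarray
    viable_mask: RegionMask
    pixel_size_um: float


def generate_serial_sections(
    seed: int,
    misregistration_um: float = 0.0,
    image_size_px: tuple[int, int] = (256, 256),
    pixel_size_um: float = 3.25,
    noise_sigma: float = 0.0,
    stain_thresholds: dict[str, float] | None = None,
    steepness: float = 12.0,
) -> SerialSections:
    """Generate a registered-serial-section stain set with known latent field.

    One smooth latent "hypoxia" field H in [0, 1] drives the three
    hypoxia stains through sigmoidal activations with stain-specific
    thresholds; the vessel stain is an independent smooth field and the
    tumor stain marks the viable region. Each stain is rigidly shifted
    by at most `misregistration_um` and independently noised.
    """
    if misregistration_um < 0:
        raise ValueError("misregistration_um must be non-negative")
    rng = np.random.default_rng(seed)
    h, w = image_size_px
    thresholds = dict(DEFAULT_STAIN_THRESHOLDS)
    if stain_thresholds:
        thresholds.update(stain_thresholds)

    def smooth_field(sigma_frac: float = 0.08) -> np.ndarray:
        raw = ndimage.gaussian_filter(
            rng.normal(size=(h, w)), sigma=sigma_frac * min(h, w)
        )
        lo, hi = raw.min(), raw.max()
        return (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)

    latent = smooth_field()
    yy, xx = np.mgrid[0:h, 0:w]
    viable = np.hypot(yy - h / 2, xx - w / 2) <= 0.42 * min(h, w)

    def activation(name: str) -> np.ndarray:
        thr = thresholds[name]
        return 1.0 / (1.0 + np.exp(-steepness * (latent - thr)))

    stains: dict[str, np.ndarray] = {
        "GFP": activation("GFP"),
        "CA9": activation("CA9"),
        "PIMO": activation("PIMO"),
        "CD31": smooth_field(0.05),
        "DsRed": viable.astype(float),
    }

    max_shift_px = misregistration_um / pixel_size_um
    for name in STAIN_NAMES:
        img = stains[name] * viable
        if max_shift_px > 0:
            shift = rng.integers(-int(max_shift_px), int(max_shift_px) + 1, size=2)
            img = np.roll(img, tuple(shift), axis=(0, 1))
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, img.shape)
        stains[name] = img
    return SerialSections(
        stains=stains,
        latent_hypoxia=latent,
        viable_mask=RegionMask(viable, pixel_size_um, "viable_tumor"),
        pixel_size_um=pixel_size_um,
    )


def generate_timecourse(
    halflife_h: float,
    baseline: float,
    amplitude: float,
    times_h: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Exponential-decay fluorescence time course.

    intensity(t) = baseline + amplitude * 2**(-t / halflife_h), with
    optional additive Gaussian noise.
    """
    if halflife_h <= 0:
        raise ValueError("halflife_h must be positive")
    t = np.asarray(times_h, dtype=float)
    intensity = baseline + amplitude * np.power(2.0, -t / halflife_h)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sigma, t.shape)
    return pd.DataFrame({"time_h": t, "intensity": intensity})
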