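import numpy as np
import pytest

from ivhypoxia import SceneParams, generate_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 256x256 noise-free scene with ground truth."""
    params = SceneParams(seed=7, image_size_px=(256, 256), n_vessels=3)
    image, truth = generate_scene(params)
    return params, image, truth


def stripe_patch(angle_deg: float, n: int = 96, period: float = 8.0) -> np.ndarray:
    """Sinusoidal stripe pattern whose ridges run along `angle_deg`."""
    yy, xx = np.mgrid[0:n, 0:n]
    th = np.deg2rad(angle_deg)
    phase = (xx * np.sin(th) + yy * np.cos(th)) * 2 * np.pi / period
    return np.cos(phase)


def brute_force_distance_map(vessel_mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Minimum Euclidean distance to any vessel pixel, by enumeration."""
    h, w = vessel_mask.shape
    vy, vx = np.nonzero(vessel_mask)
    if len(vy) == 0:
        return np.full((h, w), np.inf)
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy[..., None] - vy) ** 2 + (xx[..., None] - vx) ** 2
    return np.sqrt(d2.min(axis=-1)) * pixel_size_um
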