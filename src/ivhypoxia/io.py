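"""Reading and writing scenes, masks, and matrices.

Scenes are multi-page TIFFs (one page per channel) with a JSON sidecar
carrying pixel size, channel names, seed, and ground-truth paths;
masks are single-page 8-bit TIFFs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .roi_vasculature import RegionMask
from .spectral import SpectralImage


def write_spectral_image(
    image: SpectralImage, path: str | Path, seed: int | None = None, **extra
) -> Path:
    """Write a multichannel image as a multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, image.channels.astype(np.float32), photometric="minisblack")
    sidecar = {
        "pixel_size_um": image.pixel_size_um,
        "channel_names": image.channel_names,
        "seed": seed,
        **extra,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_spectral_image(path: str | Path) -> SpectralImage:
    """Read a multi-page TIFF with its JSON sidecar."""
    path = Path(path)
    channels = np.asarray(tifffile.imread(path), dtype=float)
    if channels.ndim == 2:
        channels = channels[None]
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        names = meta["channel_names"]
        px = float(meta["pixel_size_um"])
    else:
        names = [f"ch{i}" for i in range(channels.shape[0])]
        px = 1.0
    return SpectralImage(channels, names, px)


def write_mask(mask: RegionMask, path: str | Path) -> Path:
    """Write a binary mask as a single-page 8-bit TIFF (255 = inside)."""
    path = Path(path)
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    path.with_suffix(".json").write_text(
        json.dumps({"pixel_size_um": mask.pixel_size_um, "kind": mask.kind})
    )
    return path


def read_mask(path: str | Path, kind: str = "tumor_roi") -> RegionMask:
    path = Path(path)
    arr = np.asarray(tifffile.imread(path)) > 0
    px = 1.0
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        px = float(meta.get("pixel_size_um", 1.0))
        kind = meta.get("kind", kind)
    return RegionMask(arr, px, kind)
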