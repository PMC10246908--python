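"""Linear spectral unmixing of multichannel fluorescence images.

The measured channel signal ``S`` at each pixel is modelled as a linear
combination of fluorophore abundances ``A`` through a coefficient matrix
``R`` (fluorophores x channels)::

    S = A @ R

``R`` is estimated from single-fluorophore control images; abundances are
recovered per pixel by linear least squares.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class SpectralImage:
    """Multichannel 2D image with named channels and a physical pixel size.

    Parameters
    ----------
    channels : ndarray, shape (C, H, W)
        One 2D image per channel, stacked along the first axis.
    channel_names : list of str
        Channel labels, length C.
    pixel_size_um : float
        Physical size of one pixel in micrometres. Must be positive.
    """

    channels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3:
            raise ValueError(
                f"channels must be a (C, H, W) array, got ndim={self.channels.ndim}"
            )
        if len(self.channel_names) != self.channels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.channels.shape[0]} channels"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (H, W) shape."""
        return self.channels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the 2D image for the channel called `name`."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None
        return self.channels[idx]


@dataclass
class UnmixMatrix:
    """Fluorophore x channel coefficient matrix with unit row sums.

    Each row holds one fluorophore's relative contribution to every
    detection channel; entries are non-negative and each row sums to 1.
    """

    values: np.ndarray
    fluorophore_names: list[str]
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D (F, C) matrix")
        f, c = self.values.shape
        if len(self.fluorophore_names) != f or len(self.channel_names) != c:
            raise ValueError("name lists must match matrix dimensions")
        if np.any(self.values < 0):
            raise ValueError("coefficients must be non-negative")
        row_sums = self.values.sum(axis=1)
        if np.any(row_sums <= 0):
            raise ValueError("each row must have positive sum")
        if not np.allclose(row_sums, 1.0, atol=1e-8):
            raise ValueError("rows must be normalized to unit sum")

    @property
    def n_fluorophores(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        """Write as CSV with channel-name header and fluorophore index."""
        pd.DataFrame(
            self.values, index=self.fluorophore_names, columns=self.channel_names
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "UnmixMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), list(df.index), list(df.columns))

    @classmethod
    def normalized(
        cls,
        values: np.ndarray,
        fluorophore_names: Sequence[str],
        channel_names: Sequence[str],
    ) -> "UnmixMatrix":
        """Build from raw non-negative rows, normalizing each to unit sum."""
        values = np.asarray(values, dtype=float)
        sums = values.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("cannot normalize a row with non-positive sum")
        return cls(values / sums, list(fluorophore_names), list(channel_names))


def estimate_unmix_matrix(
    controls: Sequence[SpectralImage],
    fluorophore_names: Sequence[str] | None = None,
    background_percentile: float = 50.0,
) -> UnmixMatrix:
    """Estimate the coefficient matrix from single-fluorophore controls.

    For each control image, signal pixels are selected as those whose
    brightest-channel intensity exceeds `background_percentile` of that
    channel; the row is the mean channel-intensity vector over those
    pixels, normalized to unit sum.

    Parameters
    ----------
    controls : sequence of SpectralImage
        One control per fluorophore, all sharing the same channel set.
    fluorophore_names : sequence of str, optional
        Names for the rows; defaults to ``F0, F1, ...``.
    background_percentile : float
        Percentile of the brightest channel below which pixels are
        treated as background.

    Returns
    -------
    UnmixMatrix
    """
    if not controls:
        raise ValueError("at least one control image is required")
    channel_names = controls[0].channel_names
    for ctl in controls[1:]:
        if ctl.channel_names != channel_names:
            raise ValueError(
                "all control images must share the same channel set; "
                f"got {ctl.channel_names} vs {channel_names}"
            )
    if fluorophore_names is None:
        fluorophore_names = [f"F{i}" for i in range(len(controls))]
    if len(fluorophore_names) != len(controls):
        raise ValueError("one fluorophore name per control image")

    rows = []
    for name, ctl in zip(fluorophore_names, controls):
        stack = ctl.channels
        if not np.any(stack > 0):
            raise ValueError(f"control {name!r} has all-zero signal")
        # Brightest channel defines which pixels carry signal.
        bright_idx = int(np.argmax(stack.sum(axis=(1, 2))))
        bright = stack[bright_idx]
        cutoff = np.percentile(bright, background_percentile)
        mask = bright > cutoff
        if not mask.any():  # constant control image: use every pixel
            mask = np.ones_like(bright, dtype=bool)
        rows.append(stack[:, mask].mean(axis=1))
    return UnmixMatrix.normalized(np.array(rows), fluorophore_names, channel_names)


def mix(abundances: np.ndarray, matrix: UnmixMatrix) -> np.ndarray:
    """Forward model: mix per-fluorophore abundances into channel signals.

    Parameters
    ----------
    abundances : ndarray, shape (F, H, W)
    matrix : UnmixMatrix with F rows

    Returns
    -------
    ndarray, shape (C, H, W)
    """
    abundances = np.asarray(abundances, dtype=float)
    if abundances.shape[0] != matrix.n_fluorophores:
        raise ValueError("abundance stack does not match matrix rows")
    return np.tensordot(matrix.values.T, abundances, axes=1)


def unmix(
    image: SpectralImage,
    matrix: UnmixMatrix,
    clip_negative: bool = True,
    nonnegative: bool = False,
) -> SpectralImage:
    """Solve S = A @ R per pixel for the fluorophore abundances A.

    Parameters
    ----------
    image : SpectralImage
        Mixed image; channel count must match the matrix columns.
    matrix : UnmixMatrix
        Coefficient matrix R (fluorophores x channels); must have full
        row rank (F <= C and non-singular).
    clip_negative : bool
        Clip negative least-squares solutions to 0 (physical
        non-negativity). Ignored when `nonnegative` is set.
    nonnegative : bool
        Solve a true non-negative least-squares problem per pixel
        (slower; exact NNLS instead of clip-after-solve).

    Returns
    -------
    SpectralImage
        Per-fluorophore abundance images, same spatial shape and pixel
        size as the input.
    """
    if image.channels.shape[0] != matrix.n_channels:
        raise ValueError(
            f"image has {image.channels.shape[0]} channels but matrix "
            f"expects {matrix.n_channels}"
        )
    r = matrix.values
    f, c = r.shape
    if f > c:
        raise np.linalg.LinAlgError(
            f"matrix is rank-deficient: {f} fluorophores > {c} channels"
        )
    cond = np.linalg.cond(r)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"matrix is singular or ill-conditioned (condition number {cond:.3e})"
        )

    h, w = image.shape
    s = image.channels.reshape(c, -1)  # pixels as columns
    if nonnegative:
        from scipy.optimize import nnls

        a = np.empty((f, s.shape[1]))
        rt = r.T
        for j in range(s.shape[1]):
            a[:, j] = nnls(rt, s[:, j])[0]
    else:
        # S_px = a_px @ R  <=>  R^T a_px^T = S_px^T, solved for all pixels at once
        a, *_ = np.linalg.lstsq(r.T, s, rcond=None)
        if clip_negative:
            np.clip(a, 0.0, None, out=a)
    return SpectralImage(
        a.reshape(f, h, w), list(matrix.fluorophore_names), image.pixel_size_um
    )
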