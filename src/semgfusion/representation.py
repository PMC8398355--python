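"""Multiscale time-frequency fusion representation of multichannel sEMG.

Each channel is decomposed with an analytic (complex) Morlet continuous
wavelet transform over the functional 6-500 Hz band, one scale per grid
frequency, giving a magnitude scalogram.  The four channel scalograms are
concatenated vertically (CH1 on top) into one fused matrix, which is
bilinearly resized and colorized into a fixed-size RGB image for the
convolutional feature extractor.

The analytic Morlet has no negative-frequency content, so the magnitude
of the transform is a smooth envelope rather than an oscillating one.
Scales are chosen as ``s_i = C * fs / f_i`` (C the wavelet's centre
frequency in cycles), so the pseudo-frequency of scale ``s_i`` is exactly
the grid frequency ``f_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from matplotlib import colormaps
from skimage.transform import resize as _resize

__all__ = [
    "WaveletSpec",
    "FrequencyGrid",
    "Scalogram",
    "FusedTF",
    "RGBImage",
    "make_grid",
    "mdtfr",
    "fuse_channels",
    "render_rgb",
    "trial_to_image",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Analytic Morlet parameterization (pywt ``cmorB-C``).

    The defaults (bandwidth 4.0, centre frequency 1.5 cycles) give a
    wavelet long enough to resolve neighbouring rows of a 1 Hz frequency
    grid: pure tones localize to the nearest grid row and most of a
    tone's scalogram energy stays within a few rows of it.
    """

    bandwidth: float = 4.0
    center_frequency: float = 1.5

    def __post_init__(self) -> None:
        if self.center_frequency <= 0 or self.bandwidth <= 0:
            raise ValueError("wavelet parameters must be positive")

    @property
    def name(self) -> str:
        return f"cmor{self.bandwidth}-{self.center_frequency}"


@dataclass(frozen=True)
class FrequencyGrid:
    f_lo: float
    f_hi: float
    step: float
    fs: float
    frequencies: np.ndarray = field(repr=False)
    scales: np.ndarray = field(repr=False)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FrequencyGrid)
            and self.fs == other.fs
            and np.array_equal(self.frequencies, other.frequencies)
        )

    def __len__(self) -> int:
        return len(self.frequencies)


def make_grid(
    f_lo: float,
    f_hi: float,
    step: float,
    fs: float,
    wavelet: WaveletSpec | None = None,
) -> FrequencyGrid:
    """Ascending frequency grid with one CWT scale per frequency."""
    wavelet = wavelet or WaveletSpec()
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    if f_hi > fs / 2:
        raise ValueError(f"f_hi={f_hi} Hz exceeds Nyquist {fs / 2} Hz")
    if step <= 0:
        raise ValueError("step must be positive")
    frequencies = np.arange(f_lo, f_hi + step / 2, step)
    # pseudo-frequency of scale s is C*fs/s, so invert for the grid
    fc = pywt.central_frequency(wavelet.name)
    scales = fc * fs / frequencies
    return FrequencyGrid(
        f_lo=f_lo, f_hi=f_hi, step=step, fs=fs,
        frequencies=frequencies, scales=scales,
    )


@dataclass
class Scalogram:
    """|CWT| magnitudes: rows = grid frequencies (ascending), cols = time."""

    magnitude: np.ndarray
    grid: FrequencyGrid
    channel_id: int = 0

    def __post_init__(self) -> None:
        if self.magnitude.shape[0] != len(self.grid):
            raise ValueError("row count must match grid length")
        if not np.all(np.isfinite(self.magnitude)) or np.any(self.magnitude < 0):
            raise ValueError("magnitudes must be finite and non-negative")


def mdtfr(
    x: np.ndarray,
    fs: float,
    grid: FrequencyGrid,
    wavelet: WaveletSpec | None = None,
    channel_id: int = 0,
) -> Scalogram:
    """Multiscale decomposition of one channel into a magnitude scalogram."""
    wavelet = wavelet or WaveletSpec()
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN/Inf")
    if fs != grid.fs:
        raise ValueError("sampling rate does not match the grid")
    coeffs, _ = pywt.cwt(
        x, grid.scales, wavelet.name, sampling_period=1.0 / fs, method="fft"
    )
    return Scalogram(magnitude=np.abs(coeffs), grid=grid, channel_id=channel_id)


@dataclass
class FusedTF:
    """Vertical concatenation of channel scalograms, CH1 block on top."""

    magnitude: np.ndarray
    n_channels: int
    grid: FrequencyGrid


def fuse_channels(scalograms: list[Scalogram]) -> FusedTF:
    if not scalograms:
        raise ValueError("no scalograms to fuse")
    grid = scalograms[0].grid
    width = scalograms[0].magnitude.shape[1]
    for s in scalograms[1:]:
        if s.grid != grid or s.magnitude.shape[1] != width:
            raise ValueError("scalograms must share grid and sample count")
    fused = np.vstack([s.magnitude for s in scalograms])
    return FusedTF(magnitude=fused, n_channels=len(scalograms), grid=grid)


@dataclass
class RGBImage:
    pixels: np.ndarray  # [H, W, 3] floats in [0, 1]
    norm: str
    colormap: str

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be [H, W, 3]")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")


def render_rgb(
    fused: FusedTF,
    size: int = 224,
    norm: str = "minmax",
    colormap: str = "jet",
) -> RGBImage:
    """Resize the fused magnitude field bilinearly, normalize, colorize.

    The scalar field is resized before colorizing so interpolation happens
    in magnitude space, not colour space.  An all-zero field maps to the
    colormap's lowest colour; a non-zero constant field maps to mid-scale.
    """
    if norm not in ("minmax", "log"):
        raise ValueError("norm must be 'minmax' or 'log'")
    m = fused.magnitude
    if m.size == 0:
        raise ValueError("empty fused representation")
    if norm == "log":
        m = np.log1p(m)
    lo, hi = float(m.min()), float(m.max())
    if hi - lo <= 1e-12 * max(abs(hi), 1.0):
        # constant field: no contrast to normalize, so bypass the resize
        level = 0.0 if hi == 0.0 else 0.5
        m = np.full((size, size), level)
    else:
        m = _resize(m, (size, size), order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
        lo, hi = float(m.min()), float(m.max())
        m = (m - lo) / (hi - lo)
    cmap = colormaps[colormap]
    pixels = np.ascontiguousarray(cmap(m)[..., :3])
    return RGBImage(pixels=pixels, norm=norm, colormap=colormap)


def trial_to_image(
    data: np.ndarray,
    fs: float,
    grid: FrequencyGrid,
    wavelet: WaveletSpec | None = None,
    size: int = 224,
    norm: str = "minmax",
    colormap: str = "jet",
) -> RGBImage:
    """Full representation pipeline for one [channels x samples] trial."""
    scalos = [
        mdtfr(data[ch], fs, grid, wavelet, channel_id=ch + 1)
        for ch in range(data.shape[0])
    ]
    return render_rgb(fuse_channels(scalos), size=size, norm=norm, colormap=colormap)
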