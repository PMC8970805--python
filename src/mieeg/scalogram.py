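"""Continuous-wavelet-transform scalogram images.

A trial's channels are mapped to the channels of an H x W x C image: each EEG
channel is CWT-analysed with a complex Morlet wavelet on a log-spaced frequency
grid, the coefficient magnitudes are bilinearly resampled to the target image
size and min-max normalized to [0, 1].  With the default C3/Cz/C4 montage the
three electrodes become the R/G/B planes of a conventional 3-channel image.

Morlet center-frequency relation: scale = fs * (omega0 / 2*pi) / f.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pywt

from .errors import ConfigError, DimensionError, NyquistError
from .synth import EEGTrialSet


@dataclass
class TFRConfig:
    omega0: float = 6.0
    f_min: float = 4.0
    f_max: float = 40.0
    n_freqs: int = 64
    spacing: str = "log"            # or "linear"
    out_size: Tuple[int, int] = (224, 224)
    normalization: str = "per_channel"  # or "per_image"

    def validate(self, fs: float | None = None) -> None:
        if not 0 < self.f_min < self.f_max:
            raise ConfigError(f"need 0 < f_min < f_max, got {self.f_min}, {self.f_max}")
        if fs is not None and self.f_max >= fs / 2:
            raise NyquistError(f"f_max={self.f_max} >= Nyquist {fs / 2}")
        if self.n_freqs < 2:
            raise ConfigError(f"n_freqs must be >= 2, got {self.n_freqs}")
        if self.spacing not in ("log", "linear"):
            raise ConfigError(f"unknown spacing {self.spacing!r}")
        if self.normalization not in ("per_channel", "per_image"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if min(self.out_size) < 1:
            raise ConfigError(f"out_size must be positive, got {self.out_size}")

    def frequency_grid(self) -> np.ndarray:
        """Descending frequency grid (top image row = highest frequency)."""
        if self.spacing == "log":
            grid = np.geomspace(self.f_max, self.f_min, self.n_freqs)
        else:
            grid = np.linspace(self.f_max, self.f_min, self.n_freqs)
        return grid


@dataclass
class ScalogramImage:
    pixels: np.ndarray              # H x W x C in [0, 1]
    freqs: np.ndarray               # length H, Hz, descending
    times: np.ndarray               # length W, seconds
    channel_order: Sequence[str]

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3:
            raise DimensionError("pixels must be H x W x C")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise DimensionError("pixel values must lie in [0, 1]")


def scale_to_frequency(scale: float, omega0: float, fs: float) -> float:
    """Center frequency (Hz) of a Morlet wavelet at the given scale."""
    if scale <= 0 or omega0 <= 0 or fs <= 0:
        raise ConfigError("scale, omega0 and fs must be positive")
    return fs * (omega0 / (2 * np.pi)) / scale


def frequency_to_scale(f: float, omega0: float, fs: float) -> float:
    """Inverse of :func:`scale_to_frequency`."""
    if f <= 0 or omega0 <= 0 or fs <= 0:
        raise ConfigError("f, omega0 and fs must be positive")
    return fs * (omega0 / (2 * np.pi)) / f


def _wavelet_name(omega0: float) -> str:
    # pywt cmorB-C: exp(2*pi*i*C*t) * exp(-t^2/B); standard Morlet has
    # exp(i*omega0*t) * exp(-t^2/2)  =>  B = 2, C = omega0 / (2*pi)
    return f"cmor2.0-{omega0 / (2 * np.pi):.10f}"


def cwt(signal: np.ndarray, fs: float, cfg: TFRConfig | None = None
        ) -> Tuple[np.ndarray, np.ndarray]:
    """Morlet CWT magnitudes on the config's frequency grid.

    Returns (magnitudes n_freqs x n, freqs descending).
    """
    cfg = cfg or TFRConfig()
    cfg.validate(fs)
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise DimensionError("signal contains non-finite values")
    freqs = cfg.frequency_grid()
    scales = np.array([frequency_to_scale(f, cfg.omega0, fs) for f in freqs])
    coefs, _ = pywt.cwt(signal, scales, _wavelet_name(cfg.omega0),
                        sampling_period=1.0 / fs, method="fft")
    return np.abs(coefs), freqs


def _resize_bilinear(img: np.ndarray, out_hw: Tuple[int, int]) -> np.ndarray:
    """Separable bilinear resample of a 2-D array to (H, W)."""
    h_out, w_out = out_hw
    h_in, w_in = img.shape
    rows = np.linspace(0, h_in - 1, h_out)
    cols = np.linspace(0, w_in - 1, w_out)
    r0 = np.clip(np.floor(rows).astype(int), 0, h_in - 1)
    r1 = np.clip(r0 + 1, 0, h_in - 1)
    fr = (rows - r0)[:, None]
    tmp = img[r0, :] * (1 - fr) + img[r1, :] * fr
    c0 = np.clip(np.floor(cols).astype(int), 0, w_in - 1)
    c1 = np.clip(c0 + 1, 0, w_in - 1)
    fc = cols - c0
    return tmp[:, c0] * (1 - fc) + tmp[:, c1] * fc


def normalize_image(pixels: np.ndarray, mode: str = "per_channel") -> np.ndarray:
    """Min-max scale to [0, 1]; degenerate (constant) planes become all-zero."""
    out = np.empty_like(pixels, dtype=float)
    if mode == "per_image":
        lo, hi = pixels.min(), pixels.max()
        if hi - lo < 1e-300:
            warnings.warn("constant image; normalizing to all-zeros")
            return np.zeros_like(pixels, dtype=float)
        return (pixels - lo) / (hi - lo)
    for c in range(pixels.shape[2]):
        lo, hi = pixels[:, :, c].min(), pixels[:, :, c].max()
        if hi - lo < 1e-300:
            warnings.warn(f"constant image channel {c}; set to all-zeros")
            out[:, :, c] = 0.0
        else:
            out[:, :, c] = (pixels[:, :, c] - lo) / (hi - lo)
    return out


def make_scalogram_image(trial: np.ndarray, fs: float,
                         cfg: TFRConfig | None = None,
                         channel_order: Sequence[str] = ("C3", "Cz", "C4"),
                         ) -> ScalogramImage:
    """CWT each channel, resample to ``cfg.out_size``, min-max normalize."""
    cfg = cfg or TFRConfig()
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise DimensionError("trial must be channels x samples")
    if trial.shape[0] != len(channel_order):
        raise DimensionError(
            f"trial has {trial.shape[0]} channels, mapping names {len(channel_order)}")
    h, w = cfg.out_size
    n_ch, n_samp = trial.shape
    planes = np.empty((h, w, n_ch))
    for ch in range(n_ch):
        mag, grid = cwt(trial[ch], fs, cfg)
        planes[:, :, ch] = _resize_bilinear(mag, (h, w))
    pixels = normalize_image(planes, cfg.normalization)
    # frequency/time axes of the resampled image (index-linear interpolation
    # of the analysis grid)
    freqs = np.interp(np.linspace(0, cfg.n_freqs - 1, h),
                      np.arange(cfg.n_freqs), cfg.frequency_grid())
    times = np.interp(np.linspace(0, n_samp - 1, w),
                      np.arange(n_samp), np.arange(n_samp) / fs)
    return ScalogramImage(pixels=pixels, freqs=freqs, times=times,
                          channel_order=list(channel_order))


def batch_scalograms(ts: EEGTrialSet, cfg: TFRConfig | None = None
                     ) -> Tuple[List[ScalogramImage], np.ndarray]:
    """Order-preserving map of :func:`make_scalogram_image` over trials."""
    cfg = cfg or TFRConfig()
    images = []
    for i in range(ts.n_trials):
        try:
            images.append(make_scalogram_image(
                ts.data[i], ts.fs, cfg, channel_order=ts.channel_names))
        except Exception as exc:
            raise type(exc)(f"trial {i}: {exc}") from exc
    return images, ts.labels.copy()


def stack_pixels(images: List[ScalogramImage]) -> np.ndarray:
    """N x H x W x C array from a list of scalograms."""
    return np.stack([im.pixels for im in images])


__all__ = [
    "TFRConfig", "ScalogramImage", "cwt", "scale_to_frequency",
    "frequency_to_scale", "make_scalogram_image", "batch_scalograms",
    "normalize_image", "stack_pixels",
]
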