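"""Synthetic two-class motor-imagery EEG.

The generator emulates the canonical 3-electrode (C3, Cz, C4) cued motor-imagery
paradigm: imagining left- or right-hand movement suppresses the mu (8-12 Hz) and
beta (13-30 Hz) sensorimotor rhythms over the *contralateral* hemisphere
(event-related desynchronization, ERD).  Each trial carries

* a mu and a beta oscillation, generated as common sources with a random phase
  per trial and mixed into the channels with fixed gains (a crude stand-in for
  volume conduction, which is what makes channels linearly correlated and hence
  makes cross-channel PCA denoising meaningful);
* a multiplicative amplitude attenuation of depth ``erd_depth`` on the
  contralateral channel (C4 for left-hand imagery, C3 for right-hand), applied
  inside the imagery window with short raised-cosine ramps;
* additive 1/f^beta noise, independent per channel, scaled so that the
  full-band SNR inside the imagery window equals ``snr_db``.

Labels are integers: left = 0, right = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError

LABEL_LEFT = 0
LABEL_RIGHT = 1
LABEL_NAMES = ("left", "right")

DEFAULT_CHANNELS = ("C3", "Cz", "C4")

#: mixing gain of the common mu/beta sources into C3, Cz, C4
_CHANNEL_GAINS = np.array([1.0, 0.7, 1.0])
#: beta amplitude relative to mu
_BETA_RATIO = 0.5
#: raised-cosine ramp length (s) at the edges of the imagery window
_RAMP_S = 0.25


@dataclass
class EEGTrialSet:
    """Labeled multichannel EEG trials.

    data : (n_trials, n_channels, n_samples) float array, microvolt scale
    labels : (n_trials,) int array, values in {0 (left), 1 (right)}
    fs : sampling rate in Hz
    channel_names : ordered channel labels, length == n_channels
    trial_duration : seconds per trial; n_samples == round(fs * trial_duration)
    template : optional noiseless signal of the same shape (kept by the
        synthetic generator as a denoising oracle; never serialized)
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: Sequence[str] = DEFAULT_CHANNELS
    trial_duration: Optional[float] = None
    template: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ConfigError("data must be trials x channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ConfigError("data contains non-finite values")
        n_trials, n_ch, n_samp = self.data.shape
        if len(self.labels) != n_trials:
            raise ConfigError(
                f"labels length {len(self.labels)} != n_trials {n_trials}")
        if len(self.channel_names) != n_ch:
            raise ConfigError(
                f"channel_names length {len(self.channel_names)} != "
                f"channel axis length {n_ch}")
        if self.trial_duration is None:
            self.trial_duration = n_samp / self.fs
        if int(round(self.fs * self.trial_duration)) != n_samp:
            raise ConfigError(
                "samples != round(fs * trial_duration): "
                f"{n_samp} vs {self.fs} * {self.trial_duration}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "EEGTrialSet":
        idx = np.asarray(idx)
        return EEGTrialSet(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            channel_names=list(self.channel_names),
            trial_duration=self.trial_duration,
            template=None if self.template is None else self.template[idx],
        )


@dataclass
class SynthConfig:
    """Parameters of the synthetic MI-EEG generator (see module docstring)."""

    n_trials_per_class: int = 50
    fs: float = 128.0
    duration: float = 9.0
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    erd_depth: float = 0.5
    imagery_window: Tuple[float, float] = (3.0, 7.0)
    noise_exponent: float = 1.0
    snr_db: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials_per_class < 1:
            raise ConfigError("n_trials_per_class must be >= 1")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ConfigError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        start, end = self.imagery_window
        if not 0.0 <= start < end <= self.duration:
            raise ConfigError(
                f"imagery_window must satisfy 0 <= start < end <= duration, "
                f"got {self.imagery_window} with duration {self.duration}")
        if self.fs <= 2.0 * self.beta_freq:
            raise ConfigError(
                f"fs must exceed 2*beta_freq ({2 * self.beta_freq}), got {self.fs}")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")


def _erd_window(t: np.ndarray, start: float, end: float) -> np.ndarray:
    """Smooth 0->1->0 gate over [start, end] with raised-cosine ramps."""
    w = np.zeros_like(t)
    ramp = min(_RAMP_S, (end - start) / 2)
    inside = (t >= start) & (t <= end)
    w[inside] = 1.0
    if ramp > 0:
        up = (t >= start) & (t < start + ramp)
        w[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp))
        down = (t > end - ramp) & (t <= end)
        w[down] = 0.5 * (1 - np.cos(np.pi * (end - t[down]) / ramp))
    return w


def one_over_f_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f^exponent (spectral shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_mi_eeg(cfg: SynthConfig, include_template: bool = True) -> EEGTrialSet:
    """Generate a balanced, shuffled two-class MI trial set.

    For label ``left`` the mu/beta amplitude at C4 is attenuated by
    ``cfg.erd_depth`` inside the imagery window; for ``right`` the attenuation
    is at C3; Cz is never gated.  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_samp = int(round(cfg.fs * cfg.duration))
    t = np.arange(n_samp) / cfg.fs
    start, end = cfg.imagery_window
    gate = _erd_window(t, start, end)
    win_mask = (t >= start) & (t < end)

    n_per = cfg.n_trials_per_class
    labels = np.array([LABEL_LEFT] * n_per + [LABEL_RIGHT] * n_per)
    order = rng.permutation(2 * n_per)
    labels = labels[order]

    n_ch = len(DEFAULT_CHANNELS)
    data = np.empty((2 * n_per, n_ch, n_samp))
    template = np.empty_like(data)

    for i, lab in enumerate(labels):
        phase_mu, phase_beta = rng.uniform(0, 2 * np.pi, size=2)
        amp = rng.uniform(0.8, 1.2)  # trial-to-trial amplitude variability
        mu = amp * np.sin(2 * np.pi * cfg.mu_freq * t + phase_mu)
        beta = amp * _BETA_RATIO * np.sin(2 * np.pi * cfg.beta_freq * t + phase_beta)
        source = mu + beta
        # contralateral ERD: left imagery -> right hemisphere (C4); right -> C3
        erd_channel = 2 if lab == LABEL_LEFT else 0
        for ch in range(n_ch):
            sig = _CHANNEL_GAINS[ch] * source
            if ch == erd_channel:
                sig = sig * (1.0 - cfg.erd_depth * gate)
            template[i, ch] = sig
            noise = one_over_f_noise(n_samp, cfg.noise_exponent, rng)
            p_sig = np.mean(sig[win_mask] ** 2)
            p_noise = np.mean(noise[win_mask] ** 2)
            if p_sig > 0 and p_noise > 0:
                noise *= np.sqrt(p_sig / (p_noise * 10 ** (cfg.snr_db / 10.0)))
            data[i, ch] = sig + noise

    return EEGTrialSet(
        data=data,
        labels=labels,
        fs=cfg.fs,
        channel_names=list(DEFAULT_CHANNELS),
        trial_duration=cfg.duration,
        template=template if include_template else None,
    )


def band_power(x: np.ndarray, fs: float, f_lo: float, f_hi: float) -> float:
    """Mean periodogram power of ``x`` in [f_lo, f_hi] Hz (denoising/contrast oracle)."""
    from scipy.signal import periodogram

    f, p = periodogram(x, fs=fs)
    band = (f >= f_lo) & (f <= f_hi)
    return float(np.mean(p[band]))


__all__ = [
    "EEGTrialSet", "SynthConfig", "generate_mi_eeg", "band_power",
    "one_over_f_noise", "LABEL_LEFT", "LABEL_RIGHT", "LABEL_NAMES",
    "DEFAULT_CHANNELS",
]
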