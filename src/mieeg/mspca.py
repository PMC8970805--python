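"""Multiscale PCA (MSPCA) denoising of multichannel EEG.

Each channel of a trial is wavelet-decomposed into subbands; at every subband
the coefficients of all channels are stacked into a samples-x-channels matrix
and a PCA is fitted across channels.  Only the leading principal components
(chosen by a retention rule) are kept when re-projecting the coefficients, and
the channels are then reconstructed by the inverse wavelet transform.  Because
scalp EEG channels are linearly correlated (volume conduction) while noise is
largely independent across channels, the retained subspace keeps the shared
neural signal and discards much of the noise.

The PCA convention: for a data matrix X (n samples x m channels), columns are
mean-centered, the covariance is X_c^T X_c / (n - 1), and X_c = T P^T + E_r
with scores T = X_c P and orthonormal loadings P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple, Union

import numpy as np
import pywt

from .errors import ConfigError, DepthError, DimensionError
from .synth import EEGTrialSet

RetentionRule = Union[str, Tuple[str, float]]


@dataclass
class PCAModel:
    """Result of a PCA fit: orthonormal loadings, scores, full eigenspectrum."""

    loadings: np.ndarray        # m x A
    scores: np.ndarray          # n x A
    eigenvalues: np.ndarray     # length m, descending
    n_components: int
    column_means: np.ndarray    # length m
    residual: np.ndarray        # n x m, X_centered - T P^T

    def reconstruct(self) -> np.ndarray:
        """T P^T + column means: the rank-A approximation of the input."""
        return self.scores @ self.loadings.T + self.column_means


@dataclass
class MSPCAConfig:
    wavelet_id: str = "db4"
    levels: int = 4
    retention_rule: RetentionRule = "kaiser"
    center: bool = True
    zscore: bool = False  # divide by column std as well as centering

    def validate(self, m: int | None = None) -> None:
        if self.levels < 1:
            raise ConfigError(f"levels must be >= 1, got {self.levels}")
        kind, value = parse_rule(self.retention_rule)
        if kind == "fixed" and m is not None and value > m:
            raise ConfigError(f"fixed:{int(value)} exceeds channel count {m}")
        if kind == "variance" and not 0 < value <= 1:
            raise ConfigError(f"variance fraction must be in (0, 1], got {value}")


def parse_rule(rule: RetentionRule) -> Tuple[str, float]:
    """Normalize a retention rule to (kind, value); accepts 'kaiser',
    'fixed:A', 'variance:p' or the tuple forms."""
    if isinstance(rule, tuple):
        kind, value = rule
        return str(kind), float(value)
    if rule == "kaiser":
        return "kaiser", 0.0
    if ":" in rule:
        kind, _, value = rule.partition(":")
        if kind in ("fixed", "variance"):
            return kind, float(value)
    raise ConfigError(f"unknown retention rule {rule!r}")


def fit_pca(X: np.ndarray, n_components: Union[int, str] = "auto",
            center: bool = True, zscore: bool = False) -> PCAModel:
    """PCA of an n x m matrix via the sample covariance (n-1 denominator).

    ``n_components='auto'`` keeps all m components.  A constant (zero
    variance) input yields all-zero eigenvalues and zero scores — a valid,
    degenerate model.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DimensionError("X must be 2-D (samples x channels)")
    n, m = X.shape
    if n < 2:
        raise DimensionError(f"need at least 2 samples, got {n}")
    A = m if n_components == "auto" else int(n_components)
    if A > m or A < 1:
        raise DimensionError(f"n_components={A} out of range [1, {m}]")

    means = X.mean(axis=0) if center else np.zeros(m)
    Xc = X - means
    if zscore:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
        means = means  # reconstruction of z-scored data is out of scope here

    cov = (Xc.T @ Xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-magnitude element of each loading positive
    for j in range(m):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] *= -1

    P = eigvecs[:, :A]
    T = Xc @ P
    residual = Xc - T @ P.T
    return PCAModel(loadings=P, scores=T, eigenvalues=eigvals,
                    n_components=A, column_means=means, residual=residual)


def select_components(eigenvalues: Sequence[float], rule: RetentionRule) -> int:
    """Number of components to retain under a rule.

    kaiser      count of eigenvalues strictly above their mean (floor 1)
    fixed:A     exactly A
    variance:p  smallest A whose cumulative eigenvalue fraction reaches p
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise DimensionError("empty eigenvalue list")
    if np.any(ev < 0) or np.any(np.diff(ev) > 1e-12):
        raise DimensionError("eigenvalues must be nonnegative and descending")
    total = ev.sum()
    if total == 0:
        warnings.warn("all eigenvalues are zero; retaining 1 component")
        return 1
    kind, value = parse_rule(rule)
    if kind == "kaiser":
        return max(1, int(np.sum(ev > ev.mean())))
    if kind == "fixed":
        A = int(value)
        if not 1 <= A <= ev.size:
            raise DimensionError(f"fixed:{A} out of range [1, {ev.size}]")
        return A
    # variance:p
    frac = np.cumsum(ev) / total
    return int(np.searchsorted(frac, value - 1e-12) + 1)


def dwt_analyze(signal: np.ndarray, wavelet_id: str = "db4",
                levels: int = 4) -> List[np.ndarray]:
    """Multilevel DWT with symmetric extension.

    Returns ``[cA_L, cD_L, ..., cD_1]`` (pywt wavedec layout).  Raises
    DepthError when the signal is shorter than 2**levels.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2 ** levels:
        raise DepthError(
            f"signal of length {signal.size} too short for {levels} levels")
    return pywt.wavedec(signal, wavelet_id, mode="symmetric", level=levels)


def dwt_synthesize(subbands: List[np.ndarray], wavelet_id: str = "db4",
                   length: int | None = None) -> np.ndarray:
    """Inverse of :func:`dwt_analyze`; trims to ``length`` if given."""
    rec = pywt.waverec(subbands, wavelet_id, mode="symmetric")
    if length is not None:
        rec = rec[:length]
    return rec


def subband_frequency_ranges(fs: float, levels: int) -> List[Tuple[float, float]]:
    """Nominal (lo, hi) Hz per subband in wavedec order (approx first)."""
    ny = fs / 2
    ranges = [(0.0, ny / 2 ** levels)]
    for lev in range(levels, 0, -1):
        ranges.append((ny / 2 ** lev, ny / 2 ** (lev - 1)))
    return ranges


def mspca_denoise(ts: EEGTrialSet, cfg: MSPCAConfig | None = None) -> EEGTrialSet:
    """Denoise every trial by per-subband cross-channel PCA retention."""
    cfg = cfg or MSPCAConfig()
    m = ts.n_channels
    if m < 2:
        raise ConfigError("MSPCA needs at least 2 channels (PCA across channels)")
    cfg.validate(m)

    out = np.empty_like(ts.data)
    for i in range(ts.n_trials):
        coeffs = [dwt_analyze(ts.data[i, ch], cfg.wavelet_id, cfg.levels)
                  for ch in range(m)]
        n_bands = len(coeffs[0])
        cleaned: List[List[np.ndarray]] = [[None] * n_bands for _ in range(m)]
        for b in range(n_bands):
            band = np.stack([coeffs[ch][b] for ch in range(m)], axis=1)
            model = fit_pca(band, "auto", center=cfg.center)
            A = select_components(model.eigenvalues, cfg.retention_rule)
            approx = (model.scores[:, :A] @ model.loadings[:, :A].T
                      + model.column_means)
            for ch in range(m):
                cleaned[ch][b] = approx[:, ch]
        for ch in range(m):
            out[i, ch] = dwt_synthesize(cleaned[ch], cfg.wavelet_id,
                                        length=ts.n_samples)
    return EEGTrialSet(data=out, labels=ts.labels.copy(), fs=ts.fs,
                       channel_names=list(ts.channel_names),
                       trial_duration=ts.trial_duration,
                       template=ts.template)


__all__ = [
    "PCAModel", "MSPCAConfig", "fit_pca", "select_components",
    "dwt_analyze", "dwt_synthesize", "mspca_denoise",
    "subband_frequency_ranges", "parse_rule",
]
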