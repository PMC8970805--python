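"""Multiscale PCA: eigen-oracle equivalence, retention rules, denoising."""

import numpy as np
import pytest

from mieeg import SynthConfig, generate_mi_eeg
from mieeg.errors import ConfigError, DepthError, DimensionError
from mieeg.mspca import (MSPCAConfig, dwt_analyze, dwt_synthesize, fit_pca,
                         mspca_denoise, select_components,
                         subband_frequency_ranges)
from mieeg.synth import EEGTrialSet


# ------------------------------------------------------------------- PCA

def test_pca_matches_brute_force_eigendecomposition(rng):
    """Loadings/eigenvalues equal an explicit covariance eigendecomposition."""
    for _ in range(10):
        X = rng.normal(size=(5, 3))
        model = fit_pca(X)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        w = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(model.eigenvalues, w, atol=1e-8)
        # energy conservation: sum of eigenvalues == trace of covariance
        assert np.isclose(model.eigenvalues.sum(), np.trace(cov))
        # exact decomposition X_c = T P^T + E_r
        np.testing.assert_allclose(
            model.scores @ model.loadings.T + model.residual, Xc, atol=1e-8)
        # orthonormal loadings
        np.testing.assert_allclose(model.loadings.T @ model.loadings,
                                   np.eye(3), atol=1e-8)


def test_pca_known_2x2_covariance():
    """Data built to have sample covariance [[2,1],[1,2]] -> eigenvalues (3,1),
    first loading along (1,1)/sqrt(2)."""
    # rows chosen so the sample covariance (n-1 denominator) is exact
    base = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0],
                     [1.0, 1.0], [-1.0, -1.0]])
    X = base * np.sqrt(5.0 / 2.0)
    cov = (X - X.mean(0)).T @ (X - X.mean(0)) / (len(X) - 1)
    np.testing.assert_allclose(cov, [[2, 1], [1, 2]], atol=1e-12)
    model = fit_pca(X, 2)
    np.testing.assert_allclose(model.eigenvalues, [3.0, 1.0], atol=1e-8)
    np.testing.assert_allclose(np.abs(model.loadings[:, 0]),
                               [1 / np.sqrt(2)] * 2, atol=1e-8)


def test_duplicated_channel_gives_zero_second_eigenvalue(rng):
    x = rng.normal(size=50)
    model = fit_pca(np.column_stack([x, x]), 2)
    assert model.eigenvalues[1] < 1e-12


def test_full_rank_reconstruction_identity(rng):
    X = rng.normal(size=(20, 4))
    model = fit_pca(X, 4)
    np.testing.assert_allclose(model.reconstruct(), X, atol=1e-8)


def test_constant_input_degenerate_model():
    model = fit_pca(np.ones((10, 3)), 3)
    assert np.allclose(model.eigenvalues, 0)
    assert np.allclose(model.scores, 0)


def test_component_count_exceeding_channels_rejected(rng):
    with pytest.raises(DimensionError):
        fit_pca(rng.normal(size=(5, 3)), 4)


# -------------------------------------------------------- retention rules

@pytest.mark.parametrize("eigs,rule,expected", [
    ((3, 1), "kaiser", 1),
    ((1, 1, 1, 1), "kaiser", 1),          # floor: none strictly above mean
    ((4, 3, 2, 1), "variance:0.7", 2),     # cumulative 0.4, 0.7
    ((4, 3, 2, 1), "variance:1.0", 4),
    ((5, 4, 3), "fixed:2", 2),
])
def test_retention_rules(eigs, rule, expected):
    assert select_components(list(map(float, eigs)), rule) == expected


def test_all_zero_eigenvalues_warns_and_returns_one():
    with pytest.warns(UserWarning):
        assert select_components([0.0, 0.0], "kaiser") == 1


# ------------------------------------------------------------------- DWT

def test_dwt_perfect_reconstruction(rng):
    x = rng.normal(size=512)
    bands = dwt_analyze(x, "db4", 4)
    np.testing.assert_allclose(dwt_synthesize(bands, "db4", len(x)), x,
                               atol=1e-8)


def test_constant_signal_has_no_detail_energy():
    bands = dwt_analyze(np.full(256, 3.7), "db4", 4)
    for detail in bands[1:]:
        np.testing.assert_allclose(detail, 0, atol=1e-8)


def test_sinusoid_energy_lands_in_matching_subband():
    """A 10 Hz tone @128 Hz concentrates in the 8-16 Hz level-3 detail band.

    Checked with db8: longer Daubechies filters have the sharper band edges
    this energy-bookkeeping property needs (db4 leaks ~25% into the
    neighbouring band at a tone this close to the 8 Hz edge)."""
    fs, levels = 128.0, 4
    t = np.arange(1024) / fs
    bands = dwt_analyze(np.sin(2 * np.pi * 10 * t), "db8", levels)
    ranges = subband_frequency_ranges(fs, levels)
    energies = np.array([np.sum(b ** 2) for b in bands])
    target = next(i for i, (lo, hi) in enumerate(ranges) if lo <= 10 < hi)
    assert energies[target] / energies.sum() >= 0.8


def test_zeroing_level1_details_removes_high_frequency_power(rng):
    from scipy.signal import periodogram

    fs = 128.0
    t = np.arange(1024) / fs
    x = np.sin(2 * np.pi * 10 * t) + 0.5 * rng.normal(size=1024)
    bands = dwt_analyze(x, "db4", 4)
    bands[-1] = np.zeros_like(bands[-1])
    y = dwt_synthesize(bands, "db4", 1024)
    f, px = periodogram(x, fs)
    _, py = periodogram(y, fs)
    hi = f > 40
    assert py[hi].sum() < 0.2 * px[hi].sum()


def test_too_short_signal_raises_depth_error():
    with pytest.raises(DepthError):
        dwt_analyze(np.ones(8), "db4", 4)


def test_mismatched_wavelet_breaks_reconstruction(rng):
    """Synthesizing with a different wavelet is flagged: either the
    coefficient layout no longer matches (error) or the output is wrong."""
    x = rng.normal(size=256)
    bands = dwt_analyze(x, "db4", 3)
    try:
        y = dwt_synthesize(bands, "db2", 256)
    except ValueError:
        return
    assert np.abs(y - x).max() > 1e-6


# ---------------------------------------------------------- full denoiser

def test_full_retention_is_identity(small_trials):
    out = mspca_denoise(small_trials, MSPCAConfig(retention_rule="fixed:3"))
    np.testing.assert_allclose(out.data, small_trials.data, atol=1e-8)


def test_rank_one_mixture_preserved(rng):
    """Channels that are scalar multiples of one source pass through."""
    src = rng.normal(size=512)
    data = np.stack([np.stack([src, 0.5 * src, 2.0 * src])])
    ts = EEGTrialSet(data=data, labels=np.array([0]), fs=128.0)
    out = mspca_denoise(ts, MSPCAConfig())
    np.testing.assert_allclose(out.data, ts.data, atol=1e-6)


def test_denoising_reduces_template_mse(noisy_trials):
    """At 0 dB SNR the denoised trials are closer to the clean template."""
    den = mspca_denoise(noisy_trials)
    before = ((noisy_trials.data - noisy_trials.template) ** 2).mean(axis=(1, 2))
    after = ((den.data - noisy_trials.template) ** 2).mean(axis=(1, 2))
    assert np.mean(after < before) >= 0.9


def test_denoising_mse_monotone_in_snr():
    """Residual error to the template shrinks as the input SNR grows."""
    errs = []
    for snr in (-5.0, 0.0, 10.0):
        ts = generate_mi_eeg(SynthConfig(n_trials_per_class=10, snr_db=snr,
                                         seed=21))
        den = mspca_denoise(ts)
        errs.append(float(((den.data - ts.template) ** 2).mean()))
    assert errs[0] > errs[1] > errs[2]


def test_single_channel_input_rejected(small_trials):
    mono = EEGTrialSet(data=small_trials.data[:, :1], labels=small_trials.labels,
                       fs=small_trials.fs, channel_names=["C3"])
    with pytest.raises(ConfigError):
        mspca_denoise(mono)
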