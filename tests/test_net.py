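"""Feature extractor: backprop correctness, determinism, learnability."""

import numpy as np
import pytest

from mieeg.errors import ConfigError, ShapeError, TrainingError
from mieeg.net import (DEPTH_CONFIGS, NetConfig, accuracy,
                       build_feature_extractor, extract_features,
                       load_checkpoint, save_checkpoint, train_network)
from mieeg.net.losses import FocalLossParams, focal_loss_from_logits


def _tiny_cfg(**kw):
    base = dict(backbone_depth="tiny", fpn_dim=4, feature_dim=8, seed=0,
                epochs=2, batch_size=8, val_fraction=0.0)
    base.update(kw)
    return NetConfig(**base)


def test_same_seed_identical_parameters():
    a = build_feature_extractor(_tiny_cfg())
    b = build_feature_extractor(_tiny_cfg())
    for pa, pb in zip(a.parameters(), b.parameters()):
        np.testing.assert_array_equal(pa.value, pb.value)


def test_forward_contract(rng):
    net = build_feature_extractor(_tiny_cfg())
    logits, feats = net.forward(rng.uniform(size=(4, 16, 16, 3)))
    assert logits.shape == (4,) and feats.shape == (4, 8)
    assert np.all(np.isfinite(logits)) and np.all(np.isfinite(feats))
    probs = net.predict_proba(rng.uniform(size=(2, 16, 16, 3)))
    np.testing.assert_allclose(probs.sum(axis=1), 1.0)


def test_parameter_count_monotone_in_depth():
    counts = [build_feature_extractor(NetConfig(backbone_depth=d)).n_parameters
              for d in ("tiny", 18, 34)]
    assert counts[0] < counts[1] < counts[2]


def test_invalid_depth_rejected():
    with pytest.raises(ConfigError):
        build_feature_extractor(NetConfig(backbone_depth=7))


def test_gradients_match_numeric(rng):
    """End-to-end backprop vs central differences on sampled parameters."""
    net = build_feature_extractor(_tiny_cfg())
    x = rng.uniform(size=(3, 16, 16, 3))
    y = np.array([0, 1, 1])
    params = FocalLossParams()

    def loss():
        l, _ = focal_loss_from_logits(net.forward(x)[0], y, params)
        return l

    for mode in (False, True):
        net.set_training(mode)
        net.zero_grad()
        _, dz = focal_loss_from_logits(net.forward(x)[0], y, params)
        net.backward(dz)
        for p in net.parameters():
            flat, grad = p.value.ravel(), p.grad.ravel()
            for k in rng.choice(flat.size, size=min(2, flat.size),
                                replace=False):
                h, orig = 1e-5, flat[k]
                flat[k] = orig + h
                lp = loss()
                flat[k] = orig - h
                lm = loss()
                flat[k] = orig
                assert np.isclose((lp - lm) / (2 * h), grad[k], atol=1e-7), p.name


def test_untrained_network_near_chance(separable_scalograms):
    """epochs=0: accuracy stays in the chance band over 10 seeds."""
    pixels, labels = separable_scalograms
    accs = []
    for seed in range(10):
        cfg = NetConfig(epochs=0, seed=seed, val_fraction=0.25)
        net = build_feature_extractor(cfg)
        accs.append(train_network(net, pixels, labels, cfg).val_accuracy)
    assert 0.3 <= np.mean(accs) <= 0.7


def test_training_fits_separable_data(separable_scalograms):
    """Deep-ERD clean scalograms: >= 0.95 training accuracy in 30 epochs."""
    pixels, labels = separable_scalograms
    cfg = NetConfig(epochs=30, seed=0, val_fraction=0.0)
    net = build_feature_extractor(cfg)
    result = train_network(net, pixels, labels, cfg)
    assert accuracy(net, pixels, labels) >= 0.95
    assert result.loss_history[-1] <= result.loss_history[0]


def test_training_deterministic(separable_scalograms):
    pixels, labels = separable_scalograms
    hist = []
    for _ in range(2):
        cfg = NetConfig(epochs=3, seed=7, val_fraction=0.0)
        net = build_feature_extractor(cfg)
        hist.append(train_network(net, pixels, labels, cfg).loss_history)
    np.testing.assert_array_equal(hist[0], hist[1])


def test_single_class_input_rejected(separable_scalograms):
    pixels, labels = separable_scalograms
    keep = labels == 0
    net = build_feature_extractor(_tiny_cfg())
    with pytest.raises(TrainingError):
        train_network(net, pixels[keep], labels[keep], _tiny_cfg())


def test_feature_extraction_contract(rng):
    net = build_feature_extractor(_tiny_cfg())
    x = rng.uniform(size=(5, 16, 16, 3))
    fm = extract_features(net, x)
    assert fm.F.shape == (5, 8)
    # identical inputs give identical rows; permutation permutes rows
    fm2 = extract_features(net, x[[2, 0, 1, 4, 3]])
    np.testing.assert_allclose(fm2.F, fm.F[[2, 0, 1, 4, 3]], atol=1e-12)
    with pytest.raises(ShapeError):
        net.forward(rng.uniform(size=(2, 15, 15, 3)))


def test_checkpoint_round_trip(tmp_path, rng, separable_scalograms):
    pixels, labels = separable_scalograms
    cfg = NetConfig(epochs=2, seed=3, val_fraction=0.0)
    net = build_feature_extractor(cfg)
    train_network(net, pixels, labels, cfg)
    x = rng.uniform(size=(3, 32, 32, 3))
    ref, _ = net.forward(x)
    path = save_checkpoint(net, tmp_path / "model.ckpt")
    back = load_checkpoint(path)
    out, _ = back.forward(x)
    np.testing.assert_allclose(out, ref, atol=1e-12)
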