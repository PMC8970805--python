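"""Training loop (momentum SGD on mean focal loss) and feature extraction."""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..errors import ShapeError, TrainingError
from .losses import FocalLossParams, focal_loss_from_logits
from .model import FeatureExtractor, FeatureMatrix, NetConfig

#: global gradient-norm ceiling (guards against the occasional explosion
#: of momentum SGD on small batches)
_GRAD_CLIP = 5.0


@dataclass
class TrainResult:
    net: FeatureExtractor
    val_accuracy: float
    loss_history: List[float] = field(default_factory=list)
    hyperparams: Dict[str, float] = field(default_factory=dict)


def stratified_split(labels: np.ndarray, fraction: float,
                     rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """(train_idx, held_out_idx); per-class proportional sampling."""
    labels = np.asarray(labels)
    held = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        k = int(round(fraction * len(idx)))
        held.extend(idx[:k])
    held = np.sort(np.array(held, dtype=int))
    train = np.setdiff1d(np.arange(len(labels)), held)
    return train, held


def _recenter_bias(net: FeatureExtractor, images: np.ndarray,
                   labels: np.ndarray, batch_size: int = 32) -> None:
    """Recenter the classification-head bias on the training set.

    With a balanced two-class problem the decision threshold should sit at
    the midpoint of the per-class logit means; stochastic minibatch noise
    makes the raw bias wander by more than the logit separation on hard
    tasks, so the bias is recalibrated once after the epoch loop (a
    deterministic function of the training data)."""
    logits = []
    for lo in range(0, len(images), batch_size):
        z, _ = net.forward(images[lo:lo + batch_size])
        logits.append(z)
    z = np.concatenate(logits)
    mids = [z[labels == c].mean() for c in np.unique(labels)]
    net.dense_cls.b.value[0] -= float(np.mean(mids))


def accuracy(net: FeatureExtractor, images: np.ndarray,
             labels: np.ndarray, batch_size: int = 32) -> float:
    preds = []
    for lo in range(0, len(images), batch_size):
        logits, _ = net.forward(images[lo:lo + batch_size])
        preds.append((logits > 0).astype(int))
    return float(np.mean(np.concatenate(preds) == np.asarray(labels)))


def train_network(net: FeatureExtractor, images: np.ndarray,
                  labels: np.ndarray, cfg: Optional[NetConfig] = None,
                  hyperparams: Optional[Dict[str, float]] = None
                  ) -> TrainResult:
    """Minimize mean focal loss by momentum SGD for ``cfg.epochs`` epochs.

    ``hyperparams`` may override ``learning_rate``, ``epochs``, and the focal
    parameters ``alpha``/``gamma`` (the knobs exposed to the metaheuristic
    tuner).  A stratified validation split of ``cfg.val_fraction`` is carved
    out; validation accuracy on it is returned (training-set accuracy when
    the fraction is 0).  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or net.cfg
    labels = np.asarray(labels)
    images = np.asarray(images, dtype=float)
    if images.shape[0] != len(labels):
        raise ShapeError("images and labels length mismatch")
    classes, counts = np.unique(labels), np.bincount(labels.astype(int))
    if len(classes) < 2:
        raise TrainingError("training requires at least two classes")
    if counts.min() < 2:
        raise TrainingError("need at least 2 images per class")

    hp = dict(hyperparams or {})
    lr = float(hp.get("learning_rate", cfg.learning_rate))
    epochs = int(round(hp.get("epochs", cfg.epochs)))
    focal = FocalLossParams(alpha=float(hp.get("alpha", 0.25)),
                            gamma=float(hp.get("gamma", 2.0)))
    focal.validate()

    rng = np.random.default_rng(cfg.seed)
    if cfg.val_fraction > 0:
        tr_idx, va_idx = stratified_split(labels, cfg.val_fraction, rng)
        if len(np.unique(labels[va_idx])) < 2 or len(np.unique(labels[tr_idx])) < 2:
            tr_idx = np.arange(len(labels))
            va_idx = tr_idx
    else:
        tr_idx = np.arange(len(labels))
        va_idx = tr_idx
    x_tr, y_tr = images[tr_idx], labels[tr_idx]

    params = net.parameters()
    velocity = [np.zeros_like(p.value) for p in params]
    history: List[float] = []
    net.set_training(True)
    epoch = 0
    while epoch < epochs:
        snapshot = [p.value.copy() for p in params]
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, len(order), cfg.batch_size):
            batch = order[lo:lo + cfg.batch_size]
            net.zero_grad()
            logits, _ = net.forward(x_tr[batch])
            loss, dz = focal_loss_from_logits(logits, y_tr[batch], focal)
            net.backward(dz)
            gnorm = np.sqrt(sum(float(np.sum(p.grad ** 2)) for p in params))
            if gnorm > _GRAD_CLIP:
                for p in params:
                    p.grad *= _GRAD_CLIP / gnorm
            for v, p in zip(velocity, params):
                v *= cfg.momentum
                v -= lr * p.grad
                p.value += v
            epoch_loss += loss
            n_batches += 1
        finite = np.isfinite(epoch_loss) and all(
            np.all(np.isfinite(p.value)) for p in params)
        if not finite:
            # diverged: roll back the epoch, halve the step, reset momentum
            for p, s in zip(params, snapshot):
                p.value[:] = s
            for v in velocity:
                v[:] = 0.0
            lr *= 0.5
            if lr < 1e-6:
                raise TrainingError("training diverged at every step size")
            continue
        history.append(epoch_loss / max(n_batches, 1))
        epoch += 1

    net.set_training(False)
    if epochs > 0:
        _recenter_bias(net, x_tr, y_tr)
    val_acc = accuracy(net, images[va_idx], labels[va_idx])
    return TrainResult(net=net, val_accuracy=val_acc, loss_history=history,
                       hyperparams={"learning_rate": lr, "epochs": epochs,
                                    "alpha": focal.alpha, "gamma": focal.gamma})


def extract_features(net: FeatureExtractor, images: np.ndarray,
                     labels: Optional[np.ndarray] = None,
                     batch_size: int = 32) -> FeatureMatrix:
    """Penultimate-layer activations, one row per image (deterministic)."""
    images = np.asarray(images, dtype=float)
    rows = []
    for lo in range(0, len(images), batch_size):
        _, feats = net.forward(images[lo:lo + batch_size])
        rows.append(feats)
    return FeatureMatrix(F=np.concatenate(rows, axis=0), labels=labels)


def save_checkpoint(net: FeatureExtractor, path) -> Path:
    """Single-file archive: JSON manifest (config + seed) + parameter arrays."""
    path = Path(path)
    manifest = {"config": {**net.cfg.__dict__}, "in_channels": net.in_channels}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2))
        for i, a in enumerate(net.get_state()):
            with zf.open(f"param_{i:04d}.npy", "w") as fh:
                np.save(fh, a)
    return path


def load_checkpoint(path) -> FeatureExtractor:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        cfg_d = manifest["config"]
        if isinstance(cfg_d.get("backbone_depth"), str) and \
                cfg_d["backbone_depth"].isdigit():
            cfg_d["backbone_depth"] = int(cfg_d["backbone_depth"])
        cfg = NetConfig(**cfg_d)
        net = FeatureExtractor(cfg, in_channels=manifest["in_channels"])
        n_arrays = len(net.get_state())
        arrays = []
        for i in range(n_arrays):
            with zf.open(f"param_{i:04d}.npy") as fh:
                arrays.append(np.load(fh))
    net.set_state(arrays)
    return net


__all__ = ["TrainResult", "train_network", "extract_features",
           "stratified_split", "accuracy", "save_checkpoint", "load_checkpoint"]
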