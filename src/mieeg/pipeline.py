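"""End-to-end orchestration: simulate/load -> denoise -> scalogram ->
(optionally tune) -> train -> extract features -> discretize + ID3 ->
confusion-matrix metrics.

A single global seed fans out to per-stage seeds through a counter-based
derivation (see :func:`mieeg.config.stage_seed`), so the whole run is
deterministic and stages can be re-run in isolation.  The evaluation
protocol repeats the train/test iteration ``eval.n_iterations`` times with a
fresh stratified split (and, for synthetic data, freshly generated trials)
per iteration, then reports per-iteration metrics plus their arithmetic mean.
Hyperparameter tuning, when enabled, happens once in the first iteration and
the tuned values are reused afterwards.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .aoa import SearchSpace, tune_hyperparameters
from .config import PipelineConfig, stage_seed
from .errors import MieegError
from .id3 import (DecisionTree, apply_discretizer, build_tree, fit_discretizer,
                  predict_batch)
from .io import read_trials
from .metrics import (ClassificationMetrics, ConfusionMatrix, average_metrics,
                      confusion, metrics_from_cm)
from .mspca import mspca_denoise
from .net import (FeatureExtractor, NetConfig, build_feature_extractor,
                  extract_features, train_network)
from .scalogram import batch_scalograms, stack_pixels
from .synth import EEGTrialSet, generate_mi_eeg

log = logging.getLogger("mieeg")

# stage indices for seed derivation
_S_DATA, _S_SPLIT, _S_TUNE, _S_TRAIN = 0, 1, 2, 3


@dataclass
class IterationResult:
    cm: ConfusionMatrix
    metrics: ClassificationMetrics
    test_accuracy: float
    net_val_accuracy: float
    tree: DecisionTree
    seed: int
    hyperparams: Dict[str, float] = field(default_factory=dict)
    error: Optional[str] = None


@dataclass
class ExperimentReport:
    iterations: List[Optional[IterationResult]]
    average: Optional[ClassificationMetrics]
    config_hash: str
    seed: int

    def to_table(self) -> pd.DataFrame:
        rows, idx = [], []
        for i, it in enumerate(self.iterations):
            if it is None:
                continue
            rows.append(it.metrics.as_percent_row())
            idx.append(f"Iteration-{i + 1}")
        if self.average is not None:
            rows.append(self.average.as_percent_row())
            idx.append("Average")
        return pd.DataFrame(rows, index=idx)


def _load_trials(cfg: PipelineConfig, seed: int) -> EEGTrialSet:
    if cfg.data.source == "synthetic":
        return generate_mi_eeg(cfg.data.to_synth(seed=seed))
    return read_trials(cfg.data.path, cfg.data.format)


def _stratified_split(labels: np.ndarray, test_fraction: float,
                      rng: np.random.Generator):
    test = []
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        k = int(round(test_fraction * len(idx)))
        test.extend(idx[:k])
    test = np.sort(np.asarray(test, dtype=int))
    train = np.setdiff1d(np.arange(len(labels)), test)
    return train, test


def run_iteration(cfg: PipelineConfig, iter_seed: int,
                  hyperparams: Optional[Dict[str, float]] = None,
                  tune: bool = False) -> IterationResult:
    """One train/test repetition; returns the confusion matrix and metrics."""
    t0 = time.time()
    ts = _load_trials(cfg, stage_seed(iter_seed, _S_DATA))
    if cfg.mspca.enabled:
        ts = mspca_denoise(ts, cfg.mspca)
    images, labels = batch_scalograms(ts, cfg.tfr)
    pixels = stack_pixels(images)

    rng = np.random.default_rng(stage_seed(iter_seed, _S_SPLIT))
    tr, te = _stratified_split(labels, cfg.eval.test_fraction, rng)
    x_tr, y_tr = pixels[tr], labels[tr]
    x_te, y_te = pixels[te], labels[te]

    net_seed = stage_seed(iter_seed, _S_TRAIN)
    net_cfg = NetConfig(**{**cfg.net.__dict__, "seed": net_seed})

    if tune and cfg.aoa.enabled:
        space = SearchSpace(
            lb=[cfg.aoa.lr_log10_range[0], cfg.aoa.gamma_range[0],
                cfg.aoa.alpha_range[0], cfg.aoa.epochs_range[0]],
            ub=[cfg.aoa.lr_log10_range[1], cfg.aoa.gamma_range[1],
                cfg.aoa.alpha_range[1], cfg.aoa.epochs_range[1]],
            names=["learning_rate", "gamma", "alpha", "epochs"],
            scale=["log10", "linear", "linear", "linear"])

        def train_eval(params: Dict[str, float]) -> float:
            net = build_feature_extractor(net_cfg)
            return train_network(net, x_tr, y_tr, net_cfg, params).val_accuracy

        hyperparams, best_acc, tune_log = tune_hyperparameters(
            train_eval, space, cfg.aoa.to_aoa(stage_seed(iter_seed, _S_TUNE)))
        log.info("tuned hyperparameters %s (val acc %.3f, %d evals)",
                 hyperparams, best_acc, len(tune_log))

    net = build_feature_extractor(net_cfg)
    result = train_network(net, x_tr, y_tr, net_cfg, hyperparams)

    feats_tr = extract_features(net, x_tr, y_tr)
    feats_te = extract_features(net, x_te, y_te)
    disc = fit_discretizer(feats_tr.F, cfg.id3.n_bins)
    tree = build_tree(apply_discretizer(disc, feats_tr.F, y_tr),
                      max_depth=cfg.id3.max_depth,
                      min_samples=cfg.id3.min_samples)
    preds = predict_batch(tree, disc.transform(feats_te.F))
    cm = confusion(y_te, preds)
    m = metrics_from_cm(cm)
    log.info("iteration seed %d: test acc %.3f (%.1f s)",
             iter_seed, m.accuracy, time.time() - t0)
    return IterationResult(cm=cm, metrics=m, test_accuracy=m.accuracy,
                           net_val_accuracy=result.val_accuracy, tree=tree,
                           seed=iter_seed,
                           hyperparams=hyperparams or result.hyperparams)


def run_experiment(cfg: PipelineConfig) -> ExperimentReport:
    """The repetition protocol: n_iterations independent runs + Average row."""
    cfg.validate()
    iterations: List[Optional[IterationResult]] = []
    hyper: Optional[Dict[str, float]] = None
    for i in range(cfg.eval.n_iterations):
        iter_seed = stage_seed(cfg.seed, 100 + i)
        try:
            it = run_iteration(cfg, iter_seed, hyperparams=hyper,
                               tune=(i == 0))
            if i == 0 and cfg.aoa.enabled:
                hyper = it.hyperparams
            iterations.append(it)
        except MieegError as exc:
            log.error("iteration %d failed: %s", i + 1, exc)
            iterations.append(None)
    done = [it.metrics for it in iterations if it is not None]
    report = ExperimentReport(
        iterations=iterations,
        average=average_metrics(done) if done else None,
        config_hash=cfg.config_hash(), seed=cfg.seed)
    if cfg.out_dir:
        persist_report(report, cfg)
    return report


def persist_report(report: ExperimentReport, cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "config_hash": report.config_hash,
        "seed": report.seed,
        "version": _pkg_version,
        "iterations": [
            None if it is None else {
                "seed": it.seed,
                "confusion": it.cm.counts.tolist(),
                "metrics": it.metrics.as_percent_row(),
                "net_val_accuracy": it.net_val_accuracy,
                "hyperparams": it.hyperparams,
            }
            for it in report.iterations
        ],
        "average": None if report.average is None
        else report.average.as_percent_row(),
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))
    report.to_table().to_csv(out / "report.csv")
    (out / "manifest.json").write_text(json.dumps({
        "config_hash": report.config_hash,
        "seed": report.seed,
        "version": _pkg_version,
        "config": cfg.to_dict(),
        "artifacts": ["report.json", "report.csv"],
    }, indent=2))
    return out / "report.json"


__all__ = ["IterationResult", "ExperimentReport", "run_iteration",
           "run_experiment", "persist_report"]
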