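"""Single-file pipeline configuration: validation, defaults, YAML round-trip.

A pipeline config has nested sections mirroring each stage's own config type
(data, mspca, tfr, net, aoa, id3, eval) plus a global seed and output
directory.  Unknown keys are rejected; validation errors name the offending
``section.key``.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

from .aoa import AOAConfig
from .errors import ConfigError
from .mspca import MSPCAConfig
from .net import NetConfig
from .scalogram import TFRConfig
from .synth import SynthConfig


@dataclass
class DataConfig:
    """Data source: the synthetic generator or a trial-set file."""

    source: str = "synthetic"          # "synthetic" or "file"
    path: Optional[str] = None
    format: Optional[str] = None
    # synthetic-generator parameters (used when source == "synthetic")
    n_trials_per_class: int = 50
    fs: float = 128.0
    duration: float = 9.0
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    erd_depth: float = 0.5
    imagery_window: Tuple[float, float] = (3.0, 7.0)
    noise_exponent: float = 1.0
    snr_db: float = 5.0

    def validate(self) -> None:
        if self.source not in ("synthetic", "file"):
            raise ConfigError(f"data.source must be 'synthetic' or 'file', "
                              f"got {self.source!r}")
        if self.source == "file" and not self.path:
            raise ConfigError("data.path required when data.source is 'file'")
        if self.source == "synthetic":
            self.to_synth(seed=0).validate()

    def to_synth(self, seed: int) -> SynthConfig:
        return SynthConfig(
            n_trials_per_class=self.n_trials_per_class, fs=self.fs,
            duration=self.duration, mu_freq=self.mu_freq,
            beta_freq=self.beta_freq, erd_depth=self.erd_depth,
            imagery_window=tuple(self.imagery_window),
            noise_exponent=self.noise_exponent, snr_db=self.snr_db, seed=seed)


@dataclass
class MSPCASection(MSPCAConfig):
    enabled: bool = True


@dataclass
class AOASection:
    enabled: bool = False
    N: int = 3
    Mt: int = 3
    min_moa: float = 0.2
    max_moa: float = 0.9
    mu: float = 0.5
    alpha: float = 5.0
    # tuning box: learning rate on a log10 grid, focal gamma/alpha, epochs
    lr_log10_range: Tuple[float, float] = (-2.0, 0.0)
    gamma_range: Tuple[float, float] = (0.0, 4.0)
    alpha_range: Tuple[float, float] = (0.1, 0.9)
    epochs_range: Tuple[float, float] = (5.0, 40.0)

    def validate(self) -> None:
        AOAConfig(N=self.N, Mt=self.Mt, min_moa=self.min_moa,
                  max_moa=self.max_moa, mu=self.mu, alpha=self.alpha).validate()
        for name in ("lr_log10_range", "gamma_range", "alpha_range", "epochs_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"aoa.{name} must be (lo, hi) with lo <= hi")

    def to_aoa(self, seed: int) -> AOAConfig:
        return AOAConfig(N=self.N, Mt=self.Mt, min_moa=self.min_moa,
                         max_moa=self.max_moa, mu=self.mu, alpha=self.alpha,
                         seed=seed)


@dataclass
class ID3Section:
    n_bins: int = 10
    max_depth: Optional[int] = 5
    min_samples: int = 2

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ConfigError(f"id3.n_bins must be >= 2, got {self.n_bins}")
        if self.max_depth is not None and self.max_depth < 1:
            raise ConfigError("id3.max_depth must be >= 1 or null")
        if self.min_samples < 1:
            raise ConfigError("id3.min_samples must be >= 1")


@dataclass
class EvalSection:
    n_iterations: int = 5
    test_fraction: float = 0.5   # 50/50 stratified train/test split

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ConfigError("eval.n_iterations must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ConfigError("eval.test_fraction must be in (0, 1)")


@dataclass
class PipelineConfig:
    data: DataConfig = field(default_factory=DataConfig)
    mspca: MSPCASection = field(default_factory=MSPCASection)
    tfr: TFRConfig = field(default_factory=TFRConfig)
    net: NetConfig = field(default_factory=NetConfig)
    aoa: AOASection = field(default_factory=AOASection)
    id3: ID3Section = field(default_factory=ID3Section)
    eval: EvalSection = field(default_factory=EvalSection)
    seed: int = 0
    out_dir: Optional[str] = None

    def validate(self) -> None:
        for section in ("data", "aoa", "id3", "eval"):
            try:
                getattr(self, section).validate()
            except ConfigError as exc:
                raise ConfigError(f"{section}: {exc}") from None
        try:
            self.mspca.validate()
            self.tfr.validate(self.data.fs)
            self.net.validate()
        except ConfigError as exc:
            raise ConfigError(str(exc)) from None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for sec, key in (("data", "imagery_window"), ("tfr", "out_size"),
                         ("aoa", "lr_log10_range"), ("aoa", "gamma_range"),
                         ("aoa", "alpha_range"), ("aoa", "epochs_range")):
            d[sec][key] = list(d[sec][key])
        return d

    def dump(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        return hashlib.sha256(self.dump().encode()).hexdigest()[:16]


_SECTIONS = {
    "data": DataConfig, "mspca": MSPCASection, "tfr": TFRConfig,
    "net": NetConfig, "aoa": AOASection, "id3": ID3Section, "eval": EvalSection,
}
_TUPLE_KEYS = {"imagery_window", "out_size", "lr_log10_range", "gamma_range",
               "alpha_range", "epochs_range"}


def _build_section(cls, values: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown key {section}.{sorted(unknown)[0]}")
    coerced = {}
    for k, v in values.items():
        if k in _TUPLE_KEYS and isinstance(v, (list, tuple)):
            v = tuple(v)
        coerced[k] = v
    try:
        return cls(**coerced)
    except TypeError as exc:
        raise ConfigError(f"{section}: {exc}") from None


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw or {})
    top_known = set(_SECTIONS) | {"seed", "out_dir"}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key {sorted(unknown)[0]}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        sec = raw.get(name, {})
        if not isinstance(sec, dict):
            raise ConfigError(f"section {name} must be a mapping")
        kwargs[name] = _build_section(cls, sec, name)
    cfg = PipelineConfig(seed=int(raw.get("seed", 0)),
                         out_dir=raw.get("out_dir"), **kwargs)
    try:
        cfg.validate()
    except ConfigError as exc:
        raise ConfigError(str(exc)) from None
    return cfg


def load_config(path) -> PipelineConfig:
    """Parse and fully validate a YAML pipeline config; defaults filled in."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from None
    return config_from_dict(raw or {})


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Counter-based seed derivation so stages can be re-run in isolation."""
    ss = np.random.SeedSequence([int(global_seed), int(stage_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


__all__ = ["DataConfig", "MSPCASection", "AOASection", "ID3Section",
           "EvalSection", "PipelineConfig", "config_from_dict", "load_config",
           "stage_seed"]
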