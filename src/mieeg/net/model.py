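"""Residual backbone + feature-pyramid feature extractor.

The architecture follows the single-stage-detector recipe reduced to a
classifier: a residual backbone yields feature maps at several spatial
resolutions, a feature pyramid network (FPN) merges the top ``fpn_levels``
stages top-down with lateral 1x1 convolutions, and two heads sit on the
global-average-pooled finest merge: a feature head (width ``feature_dim``,
the vector handed to the downstream decision tree) and a 1-logit
classification head trained with focal loss.  Detection-specific machinery
(anchors, box regression) is intentionally absent.

Depths: ``tiny`` is an 8-conv desk-scale backbone; 18/34 use basic residual
blocks and 50/101 bottleneck blocks with the standard stage layouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np

from ..errors import ConfigError, ShapeError
from .layers import (BasicBlock, BatchNorm2D, BottleneckBlock, Conv2D,
                     Dense, GlobalAvgPool, Param, ReLU, UpsampleNearest2x)

# depth key -> (block kind, blocks per stage, stage channels/planes, stem width)
DEPTH_CONFIGS = {
    "tiny": ("basic", (1, 1, 1), (16, 32, 64), 8),
    18: ("basic", (2, 2, 2, 2), (64, 128, 256, 512), 64),
    34: ("basic", (3, 4, 6, 3), (64, 128, 256, 512), 64),
    50: ("bottleneck", (3, 4, 6, 3), (64, 128, 256, 512), 64),
    101: ("bottleneck", (3, 4, 23, 3), (64, 128, 256, 512), 64),
}


@dataclass
class NetConfig:
    backbone_depth: Union[str, int] = "tiny"
    fpn_levels: int = 3
    fpn_dim: int = 32
    feature_dim: int = 256
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 0.05
    momentum: float = 0.9
    val_fraction: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.backbone_depth not in DEPTH_CONFIGS:
            raise ConfigError(
                f"unknown backbone_depth {self.backbone_depth!r}; "
                f"expected one of {sorted(map(str, DEPTH_CONFIGS))}")
        n_stages = len(DEPTH_CONFIGS[self.backbone_depth][1])
        if not 1 <= self.fpn_levels <= n_stages:
            raise ConfigError(
                f"fpn_levels must be in [1, {n_stages}], got {self.fpn_levels}")
        if self.feature_dim < 2:
            raise ConfigError(f"feature_dim must be >= 2, got {self.feature_dim}")
        if self.epochs < 0:
            raise ConfigError(f"epochs must be >= 0, got {self.epochs}")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if not 0 <= self.val_fraction < 1:
            raise ConfigError("val_fraction must be in [0, 1)")


@dataclass
class FeatureMatrix:
    """Trials x d feature vectors with aligned labels."""

    F: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if not np.all(np.isfinite(self.F)):
            raise ShapeError("feature matrix contains non-finite values")
        if self.labels is not None and len(self.labels) != self.F.shape[0]:
            raise ShapeError("labels length must equal feature row count")


class FeatureExtractor:
    """The network handle: owns layers, runs forward/backward passes."""

    def __init__(self, cfg: NetConfig, in_channels: int = 3):
        cfg.validate()
        self.cfg = cfg
        self.in_channels = in_channels
        rng = np.random.default_rng(cfg.seed)

        kind, blocks, channels, stem_ch = DEPTH_CONFIGS[cfg.backbone_depth]
        self.stem = Conv2D(in_channels, stem_ch, 3, 1, rng, "stem")
        self.stem_bn = BatchNorm2D(stem_ch, "stem.bn")
        self.stem_relu = ReLU()

        self.stages: List[List] = []
        cin = stem_ch
        stage_out = []
        for si, (n_blocks, ch) in enumerate(zip(blocks, channels)):
            stage = []
            # 4-stage layouts keep stage 1 at full resolution (classic recipe)
            first_stride = 1 if (si == 0 and len(blocks) == 4) else 2
            for bi in range(n_blocks):
                stride = first_stride if bi == 0 else 1
                if kind == "basic":
                    blk = BasicBlock(cin, ch, stride, rng, f"s{si}b{bi}")
                    cin = ch
                else:
                    blk = BottleneckBlock(cin, ch, stride, rng, f"s{si}b{bi}")
                    cin = blk.cout
                stage.append(blk)
            self.stages.append(stage)
            stage_out.append(cin)

        self.merge_offset = len(self.stages) - cfg.fpn_levels
        merged_out = stage_out[self.merge_offset:]
        self.laterals = [Conv2D(c, cfg.fpn_dim, 1, 1, rng, f"lat{i}")
                         for i, c in enumerate(merged_out)]
        self.upsamples = [UpsampleNearest2x() for _ in range(len(merged_out) - 1)]
        self.smooth = Conv2D(cfg.fpn_dim, cfg.fpn_dim, 3, 1, rng, "smooth")
        self.gap = GlobalAvgPool()
        self.dense_feat = Dense(cfg.fpn_dim, cfg.feature_dim, rng, "feat")
        self.relu_feat = ReLU()
        self.dense_cls = Dense(cfg.feature_dim, 1, rng, "cls")

    # ------------------------------------------------------------- plumbing
    def parameters(self) -> List[Param]:
        out = self.stem.params() + self.stem_bn.params()
        for stage in self.stages:
            for blk in stage:
                out += blk.params()
        for lat in self.laterals:
            out += lat.params()
        out += (self.smooth.params() + self.dense_feat.params()
                + self.dense_cls.params())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[:] = 0.0

    # -------------------------------------------------------------- forward
    def forward(self, images: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """images (N, H, W, C) in [0,1] -> (logits (N,), features (N, d))."""
        x = np.asarray(images, dtype=float)
        if x.ndim != 4 or x.shape[3] != self.in_channels:
            raise ShapeError(
                f"expected (N, H, W, {self.in_channels}) images, got {x.shape}")
        if x.shape[1] % 8 or x.shape[2] % 8:
            raise ShapeError("image height/width must be divisible by 8")
        x = x.transpose(0, 3, 1, 2)
        x = self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x)))
        cs = []
        for stage in self.stages:
            for blk in stage:
                x = blk.forward(x)
            cs.append(x)
        self._merged_shapes = []

        merged = cs[self.merge_offset:]
        p = self.laterals[-1].forward(merged[-1])
        for i in range(len(merged) - 2, -1, -1):
            lat = self.laterals[i].forward(merged[i])
            up = self.upsamples[i].forward(p, lat.shape[2:])
            p = lat + up
        p = self.smooth.forward(p)
        pooled = self.gap.forward(p)
        feats = self.relu_feat.forward(self.dense_feat.forward(pooled))
        logits = self.dense_cls.forward(feats)[:, 0]
        return logits, feats

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Per-image probability pairs, columns (P(class 0), P(class 1)); rows sum to 1."""
        logits, _ = self.forward(images)
        p1 = 1.0 / (1.0 + np.exp(-logits))
        return np.column_stack([1 - p1, p1])  # columns: class 0 (left), class 1 (right)

    # ------------------------------------------------------------- backward
    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        g = self.dense_cls.backward(np.asarray(dlogits)[:, None])
        g = self.dense_feat.backward(self.relu_feat.backward(g))
        g = self.gap.backward(g)
        g = self.smooth.backward(g)

        n_merged = len(self.laterals)
        dcs = [None] * len(self.stages)
        for i in range(n_merged):
            dlat = self.laterals[i].backward(g)
            dcs[self.merge_offset + i] = dlat
            if i < n_merged - 1:
                g = self.upsamples[i].backward(g)

        g = dcs[-1]
        for si in range(len(self.stages) - 1, -1, -1):
            for blk in reversed(self.stages[si]):
                g = blk.backward(g)
            if si > 0 and dcs[si - 1] is not None:
                g = g + dcs[si - 1]
        self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(g)))

    # -------------------------------------------------- mode / state dict
    def bn_layers(self) -> List[BatchNorm2D]:
        out = [self.stem_bn]
        for stage in self.stages:
            for blk in stage:
                out += [l for l in blk.sublayers() if isinstance(l, BatchNorm2D)]
        return out

    def set_training(self, flag: bool) -> None:
        for bn in self.bn_layers():
            bn.training = flag

    def get_state(self) -> List[np.ndarray]:
        arrays = [p.value.copy() for p in self.parameters()]
        for bn in self.bn_layers():
            arrays += [b.copy() for b in bn.buffers()]
        return arrays

    def set_state(self, arrays: List[np.ndarray]) -> None:
        params = self.parameters()
        buffers = [b for bn in self.bn_layers() for b in bn.buffers()]
        if len(arrays) != len(params) + len(buffers):
            raise ShapeError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ShapeError(f"shape mismatch for {p.name}")
            p.value[:] = a
        for b, a in zip(buffers, arrays[len(params):]):
            if b.shape != a.shape:
                raise ShapeError("buffer shape mismatch")
            b[:] = a


def build_feature_extractor(cfg: NetConfig | None = None,
                            in_channels: int = 3,
                            seed: Optional[int] = None) -> FeatureExtractor:
    """Construct a network with deterministic initialization under ``seed``."""
    cfg = cfg or NetConfig()
    if seed is not None:
        cfg = NetConfig(**{**cfg.__dict__, "seed": seed})
    return FeatureExtractor(cfg, in_channels=in_channels)


__all__ = ["NetConfig", "FeatureMatrix", "FeatureExtractor",
           "build_feature_extractor", "DEPTH_CONFIGS"]
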