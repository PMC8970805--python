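"""ID3 decision-tree classification over nominal attributes.

At every node the attribute with maximal information gain

    gain(A) = I(S) - E(A),   I(S) = -sum_i p_i log2 p_i,
    E(A) = sum_j |S_j|/|S| * I(S_j)

is chosen as the split (ties broken toward the lowest attribute index), each
attribute value becomes a branch, and no attribute repeats along a path.
Leaves carry the majority label (ties toward the lowest class index); unseen
attribute values at prediction time fall back to the node's majority label.

Continuous feature vectors are bridged to nominal attributes by per-feature
equal-frequency (quantile) binning fitted on training data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .errors import ConfigError, DimensionError, ShapeError


# ----------------------------------------------------------------- dataset

@dataclass
class NominalDataset:
    """Rows of nominal attribute values plus integer class labels."""

    samples: np.ndarray            # n x k, integer-coded nominal values
    labels: np.ndarray             # length n
    attribute_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.labels = np.asarray(self.labels)
        if self.samples.ndim != 2:
            raise DimensionError("samples must be 2-D (rows x attributes)")
        if len(self.labels) != self.samples.shape[0]:
            raise DimensionError("labels length != sample count")
        if len(self.labels) == 0:
            raise DimensionError("dataset must be nonempty")
        if self.attribute_names is None:
            self.attribute_names = [f"a{j}" for j in range(self.samples.shape[1])]

    @property
    def n_attributes(self) -> int:
        return self.samples.shape[1]


# ---------------------------------------------------------- entropy / gain

def entropy(labels) -> float:
    """Shannon entropy in bits; 0*log2(0) taken as 0."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise DimensionError("entropy of an empty label list is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def expected_entropy(S: NominalDataset, attribute: Union[int, str]) -> float:
    """Weighted subset entropy E(A) = sum_j |S_j|/|S| I(S_j)."""
    a = _attr_index(S, attribute)
    col = S.samples[:, a]
    n = len(S.labels)
    total = 0.0
    for v in np.unique(col):
        mask = col == v
        total += mask.sum() / n * entropy(S.labels[mask])
    return float(total)


def info_gain(S: NominalDataset, attribute: Union[int, str]) -> float:
    """entropy(S) - expected_entropy(S, A); nonnegative."""
    return entropy(S.labels) - expected_entropy(S, attribute)


def _attr_index(S: NominalDataset, attribute: Union[int, str]) -> int:
    if isinstance(attribute, str):
        try:
            return list(S.attribute_names).index(attribute)
        except ValueError:
            raise KeyError(f"unknown attribute {attribute!r}") from None
    a = int(attribute)
    if not 0 <= a < S.n_attributes:
        raise KeyError(f"attribute index {a} out of range")
    return a


# ------------------------------------------------------------- discretizer

@dataclass
class DiscretizerModel:
    """Per-feature interior bin edges from training quantiles (open outer bins)."""

    edges: List[np.ndarray]
    n_bins: int

    def transform(self, F: np.ndarray) -> np.ndarray:
        F = np.asarray(F, dtype=float)
        if F.ndim != 2 or F.shape[1] != len(self.edges):
            raise ShapeError(
                f"expected {len(self.edges)}-column feature matrix, got {F.shape}")
        out = np.empty(F.shape, dtype=np.int64)
        for j, e in enumerate(self.edges):
            out[:, j] = np.searchsorted(e, F[:, j], side="right")
        return out


def fit_discretizer(F: np.ndarray, n_bins: int = 10) -> DiscretizerModel:
    """Equal-frequency binning per feature; constant features collapse to one bin."""
    if n_bins < 2:
        raise ConfigError(f"n_bins must be >= 2, got {n_bins}")
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ShapeError("feature matrix contains non-finite values")
    edges: List[np.ndarray] = []
    for j in range(F.shape[1]):
        col = F[:, j]
        if col.max() == col.min():
            warnings.warn(f"feature {j} is constant; using a single bin")
            edges.append(np.array([]))
            continue
        qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
        # strictly increasing interior edges (ties collapse bins)
        edges.append(np.unique(qs))
    return DiscretizerModel(edges=edges, n_bins=n_bins)


def apply_discretizer(model: DiscretizerModel, F: np.ndarray,
                      labels: Optional[np.ndarray] = None) -> NominalDataset:
    """Map continuous features to bin indices (out-of-range -> outer bins)."""
    binned = model.transform(F)
    if labels is None:
        labels = np.zeros(binned.shape[0], dtype=int)
    return NominalDataset(samples=binned, labels=np.asarray(labels))


# ------------------------------------------------------------------- tree

@dataclass
class TreeNode:
    label: Optional[int] = None                 # leaf label
    attribute: Optional[int] = None             # split attribute index
    children: Dict[int, "TreeNode"] = field(default_factory=dict)
    majority: int = 0                           # fallback label

    @property
    def is_leaf(self) -> bool:
        return self.attribute is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"label": int(self.label)}
        return {
            "attribute": int(self.attribute),
            "majority": int(self.majority),
            "children": {str(k): v.to_dict() for k, v in self.children.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "label" in d:
            return cls(label=int(d["label"]))
        node = cls(attribute=int(d["attribute"]), majority=int(d["majority"]))
        node.children = {int(k): cls.from_dict(v) for k, v in d["children"].items()}
        return node


@dataclass
class DecisionTree:
    root: TreeNode
    depth: int
    attribute_names: Sequence[str]
    metadata: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "root": self.root.to_dict(),
            "depth": self.depth,
            "attribute_names": list(self.attribute_names),
            "metadata": self.metadata,
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "DecisionTree":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls(root=TreeNode.from_dict(d["root"]), depth=d["depth"],
                   attribute_names=d["attribute_names"],
                   metadata=d.get("metadata", {}))


def _majority(labels: np.ndarray) -> int:
    values, counts = np.unique(labels, return_counts=True)
    return int(values[np.argmax(counts)])  # unique is sorted -> lowest wins ties


def _grow(samples: np.ndarray, labels: np.ndarray, available: List[int],
          max_depth: Optional[int], min_samples: int, depth: int) -> TreeNode:
    maj = _majority(labels)
    if (len(np.unique(labels)) == 1 or not available
            or (max_depth is not None and depth >= max_depth)
            or len(labels) < min_samples):
        return TreeNode(label=maj)

    gains = []
    base = entropy(labels)
    for a in available:
        col = samples[:, a]
        e = 0.0
        for v in np.unique(col):
            mask = col == v
            e += mask.sum() / len(labels) * entropy(labels[mask])
        gains.append(base - e)
    # argmax keeps the first (lowest) index on ties; zero-gain splits are
    # allowed (classic ID3) — XOR-style data needs them to memorize
    best = int(np.argmax(gains))
    attr = available[best]

    node = TreeNode(attribute=attr, majority=maj)
    remaining = [a for a in available if a != attr]
    for v in np.unique(samples[:, attr]):
        mask = samples[:, attr] == v
        node.children[int(v)] = _grow(samples[mask], labels[mask], remaining,
                                      max_depth, min_samples, depth + 1)
    return node


def build_tree(S: NominalDataset, max_depth: Optional[int] = None,
               min_samples: int = 1) -> DecisionTree:
    """Grow an ID3 tree (no pruning); stops on purity, attribute exhaustion,
    ``max_depth`` or ``min_samples``."""
    root = _grow(S.samples, S.labels, list(range(S.n_attributes)),
                 max_depth, min_samples, 0)

    def _depth(node: TreeNode) -> int:
        if node.is_leaf:
            return 0
        return 1 + max(_depth(c) for c in node.children.values())

    return DecisionTree(root=root, depth=_depth(root),
                        attribute_names=list(S.attribute_names),
                        metadata={"n_train": len(S.labels),
                                  "max_depth": max_depth,
                                  "min_samples": min_samples})


def predict(tree: DecisionTree, sample: Sequence[int]) -> int:
    """Follow the path; unseen branch values fall back to the node majority."""
    node = tree.root
    sample = np.asarray(sample)
    while not node.is_leaf:
        v = int(sample[node.attribute])
        child = node.children.get(v)
        if child is None:
            return node.majority
        node = child
    return int(node.label)


def predict_batch(tree: DecisionTree, dataset: Union[NominalDataset, np.ndarray]
                  ) -> np.ndarray:
    rows = dataset.samples if isinstance(dataset, NominalDataset) else np.asarray(dataset)
    return np.array([predict(tree, row) for row in rows])


__all__ = ["NominalDataset", "DiscretizerModel", "DecisionTree", "TreeNode",
           "entropy", "expected_entropy", "info_gain", "fit_discretizer",
           "apply_discretizer", "build_tree", "predict", "predict_batch"]
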