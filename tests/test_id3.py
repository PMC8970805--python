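"""ID3: entropy/gain oracles, tree growth, discretizer, prediction."""

import itertools
import json

import numpy as np
import pytest

from mieeg.errors import DimensionError, ShapeError
from mieeg.id3 import (DecisionTree, NominalDataset, apply_discretizer,
                       build_tree, entropy, expected_entropy, fit_discretizer,
                       info_gain, predict, predict_batch)


def brute_entropy(labels):
    """Independent oracle: literal -sum p_i log2 p_i over class frequencies."""
    labels = list(labels)
    out = 0.0
    for c in set(labels):
        p = labels.count(c) / len(labels)
        out -= p * np.log2(p)
    return out


def brute_expected_entropy(samples, labels, attr):
    vals = {row[attr] for row in samples}
    out = 0.0
    for v in vals:
        sub = [lab for row, lab in zip(samples, labels) if row[attr] == v]
        out += len(sub) / len(labels) * brute_entropy(sub)
    return out


def test_entropy_worked_examples():
    assert entropy([1, 1, 1]) == 0.0
    assert entropy([0, 1]) == pytest.approx(1.0)
    counts_9_5 = [0] * 9 + [1] * 5
    assert entropy(counts_9_5) == pytest.approx(0.9403, abs=5e-5)


def test_entropy_empty_rejected():
    with pytest.raises(DimensionError):
        entropy([])


def test_expected_entropy_worked_example():
    """{(A=0,y=0),(A=0,y=1),(A=1,y=1),(A=1,y=1)} -> 0.5 bits; gain 0.3113."""
    S = NominalDataset(samples=np.array([[0], [0], [1], [1]]),
                       labels=np.array([0, 1, 1, 1]))
    assert expected_entropy(S, 0) == pytest.approx(0.5)
    assert entropy(S.labels) == pytest.approx(0.8113, abs=5e-5)
    assert info_gain(S, 0) == pytest.approx(0.3113, abs=5e-5)


def test_constant_attribute_zero_gain():
    S = NominalDataset(samples=np.zeros((6, 1), dtype=int),
                       labels=np.array([0, 0, 1, 1, 0, 1]))
    assert expected_entropy(S, 0) == pytest.approx(entropy(S.labels))
    assert info_gain(S, 0) == pytest.approx(0.0, abs=1e-12)


def test_perfect_separator_full_gain():
    S = NominalDataset(samples=np.array([[0], [0], [1], [1]]),
                       labels=np.array([0, 0, 1, 1]))
    assert expected_entropy(S, 0) == 0.0
    assert info_gain(S, 0) == pytest.approx(1.0)


def test_unknown_attribute_key_error():
    S = NominalDataset(samples=np.zeros((2, 1), dtype=int),
                       labels=np.array([0, 1]))
    with pytest.raises(KeyError):
        expected_entropy(S, 3)
    with pytest.raises(KeyError):
        info_gain(S, "nope")


def test_entropy_gain_match_brute_force_enumeration():
    """Exhaustive tiny datasets: 4 rows, 2 binary attributes, binary labels."""
    for sample_bits in itertools.product([0, 1], repeat=4):
        for label_bits in itertools.product([0, 1], repeat=4):
            samples = np.array([[b, 1 - b] for b in sample_bits])
            labels = np.array(label_bits)
            S = NominalDataset(samples=samples, labels=labels)
            assert entropy(labels) == pytest.approx(
                brute_entropy(label_bits), abs=1e-12)
            for a in range(2):
                assert expected_entropy(S, a) == pytest.approx(
                    brute_expected_entropy(samples.tolist(), label_bits, a),
                    abs=1e-12)
                gain = info_gain(S, a)
                assert gain >= -1e-12
                assert gain <= entropy(labels) + 1e-12


# ------------------------------------------------------------------- tree

def test_pure_labels_single_leaf():
    S = NominalDataset(samples=np.array([[0, 1], [1, 0]]),
                       labels=np.array([1, 1]))
    tree = build_tree(S)
    assert tree.root.is_leaf and tree.root.label == 1
    assert tree.depth == 0


def test_xor_memorized_at_depth_two():
    S = NominalDataset(samples=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
                       labels=np.array([0, 1, 1, 0]))
    tree = build_tree(S)
    assert tree.depth == 2
    assert np.array_equal(predict_batch(tree, S), S.labels)


def test_memorization_without_conflicts(rng):
    """Unlimited depth: any conflict-free dataset is fit exactly."""
    samples = np.array(list(itertools.product([0, 1, 2], repeat=3)))
    labels = rng.integers(0, 2, size=len(samples))
    S = NominalDataset(samples=samples, labels=labels)
    tree = build_tree(S)
    assert np.array_equal(predict_batch(tree, S), labels)


def test_max_depth_and_min_samples_stop_growth():
    samples = np.array(list(itertools.product([0, 1], repeat=4)))
    labels = (samples.sum(axis=1) % 2).astype(int)
    S = NominalDataset(samples=samples, labels=labels)
    assert build_tree(S, max_depth=2).depth <= 2
    assert build_tree(S, min_samples=20).depth == 0


def test_unseen_branch_value_falls_back_to_majority():
    S = NominalDataset(samples=np.array([[0], [0], [1]]),
                       labels=np.array([0, 0, 1]))
    tree = build_tree(S)
    assert predict(tree, [7]) == 0  # node majority


def test_attribute_order_invariance_up_to_tiebreak():
    samples = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    labels = np.array([0, 0, 1, 1])  # attribute 0 is the perfect split
    t1 = build_tree(NominalDataset(samples=samples, labels=labels))
    t2 = build_tree(NominalDataset(samples=samples[:, ::-1], labels=labels))
    assert t1.root.attribute == 0 and t2.root.attribute == 1
    assert t1.depth == t2.depth == 1


def test_batch_equals_single_calls(rng):
    samples = rng.integers(0, 3, size=(12, 3))
    labels = rng.integers(0, 2, size=12)
    S = NominalDataset(samples=samples, labels=labels)
    tree = build_tree(S, max_depth=2)
    batch = predict_batch(tree, S)
    singles = [predict(tree, row) for row in samples]
    assert np.array_equal(batch, singles)


def test_json_round_trip(tmp_path, rng):
    samples = rng.integers(0, 2, size=(8, 3))
    labels = rng.integers(0, 2, size=8)
    S = NominalDataset(samples=samples, labels=labels)
    tree = build_tree(S)
    path = tmp_path / "tree.json"
    tree.to_json(path)
    back = DecisionTree.from_json(path)
    assert np.array_equal(predict_batch(back, S), predict_batch(tree, S))
    assert json.loads(tree.to_json())["depth"] == tree.depth


# ------------------------------------------------------------ discretizer

def test_two_bins_split_at_median(rng):
    x = rng.normal(size=(101, 1))
    model = fit_discretizer(x, n_bins=2)
    assert model.edges[0][0] == pytest.approx(np.median(x))
    binned = model.transform(x)
    assert set(np.unique(binned)) <= {0, 1}


def test_equal_frequency_occupancy(rng):
    x = rng.normal(size=(1000, 2))
    model = fit_discretizer(x, n_bins=10)
    binned = model.transform(x)
    for j in range(2):
        counts = np.bincount(binned[:, j], minlength=10)
        assert counts.min() >= 90 and counts.max() <= 110


def test_monotone_transform_invariance(rng):
    x = rng.normal(size=(64, 1))
    a = fit_discretizer(x, 4).transform(x)
    y = np.exp(x)  # strictly increasing map
    b = fit_discretizer(y, 4).transform(y)
    assert np.array_equal(a, b)


def test_constant_feature_single_bin_warning():
    F = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.warns(UserWarning):
        model = fit_discretizer(F, 4)
    assert model.edges[0].size == 0
    assert np.all(model.transform(F)[:, 0] == 0)


def test_out_of_range_values_go_to_outer_bins(rng):
    x = rng.uniform(size=(50, 1))
    model = fit_discretizer(x, 5)
    out = model.transform(np.array([[-10.0], [10.0]]))
    assert out[0, 0] == 0
    assert out[1, 0] == len(model.edges[0])


def test_apply_discretizer_builds_dataset(rng):
    F = rng.normal(size=(20, 3))
    labels = rng.integers(0, 2, size=20)
    model = fit_discretizer(F, 4)
    S = apply_discretizer(model, F, labels)
    assert S.samples.shape == (20, 3)
    assert np.array_equal(S.labels, labels)
    with pytest.raises(ShapeError):
        model.transform(rng.normal(size=(5, 2)))
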