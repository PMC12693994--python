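"""Exact LP separability oracle and the empirical SVM criterion."""

import numpy as np
import pytest
from sklearn.svm import SVC

from neurotwist.separability import (
    count_separable_rules,
    is_linearly_separable_exact,
    separable_rule_ids_3d,
    svm_separable,
)
from neurotwist.stimulus_space import enumerate_rules, feature_partition
from neurotwist.twist_algebra import twist_expand


def hard_margin_svm_separable(P, y):
    """Independent near-oracle: a hard-margin SVM (huge C) reaches zero
    training error exactly on separable sets."""
    clf = SVC(kernel="linear", C=1e8)
    clf.fit(P, y)
    return bool(np.all(clf.predict(P) == y))


def test_oracle_agrees_with_hard_margin_svm_on_random_sets():
    rng = np.random.default_rng(0)
    n_agree = 0
    for _ in range(60):
        d = rng.integers(2, 5)
        n = rng.integers(4, 10)
        P = rng.standard_normal((n, d))
        y = rng.choice([-1.0, 1.0], n)
        if np.unique(y).size < 2:
            continue
        assert is_linearly_separable_exact(P, y).separable == hard_margin_svm_separable(P, y)
        n_agree += 1
    assert n_agree > 40


def test_oracle_witness_strictly_separates(cube_points):
    P = np.array([cube_points[i] for i in range(1, 9)])
    rule = feature_partition("HV")
    y = np.array([rule.label_of(i) for i in range(1, 9)], float)
    res = is_linearly_separable_exact(P, y)
    assert res.separable
    margins = y * (P @ res.witness_normal + res.witness_offset)
    assert np.all(margins >= 1.0 - 1e-9)


def test_feature_axes_separable_but_contour_orientation_not(cube_points):
    P = np.array([cube_points[i] for i in range(1, 9)])
    for axis in ("HV", "OI", "CA"):
        rule = feature_partition(axis)
        y = [rule.label_of(i) for i in range(1, 9)]
        assert is_linearly_separable_exact(P, y).separable
    lr = feature_partition("LR")
    y = [lr.label_of(i) for i in range(1, 9)]
    assert not is_linearly_separable_exact(P, y).separable


def test_single_class_is_separable(cube_points):
    P = np.array([cube_points[i] for i in range(1, 9)])
    assert is_linearly_separable_exact(P, np.ones(8)).separable


def test_oracle_input_validation():
    with pytest.raises(ValueError):
        is_linearly_separable_exact(np.empty((0, 3)), [])
    with pytest.raises(ValueError):
        is_linearly_separable_exact([[1, 0], [0, 1]], [1])
    with pytest.raises(ValueError):
        is_linearly_separable_exact([[1, 0], [0, 1]], [1, 2])


def test_counts_in_3d_and_7d(cube_points, expanded_points, all_rules):
    assert count_separable_rules(cube_points, all_rules) == (104, 152)
    assert count_separable_rules(expanded_points, all_rules) == (256, 0)


def test_missing_vertex_rejected(cube_points, all_rules):
    pts = dict(cube_points)
    del pts[3]
    with pytest.raises(ValueError, match="missing"):
        count_separable_rules(pts, all_rules)


def test_complement_rules_share_separability(cube_points):
    sep3 = separable_rule_ids_3d()
    for rule in enumerate_rules():
        assert (rule.rule_id in sep3) == (rule.complement().rule_id in sep3)


def test_separability_is_monotone_in_embedding_dimension(cube_points, expanded_points, all_rules):
    """A rule separable in a subspace stays separable in any superspace."""
    P3 = np.array([cube_points[i] for i in range(1, 9)])
    P7 = np.array([expanded_points[i] for i in range(1, 9)])
    for rule in all_rules[::7]:
        y = [rule.label_of(i) for i in range(1, 9)]
        if is_linearly_separable_exact(P3, y).separable:
            assert is_linearly_separable_exact(P7, y).separable


def test_svm_criterion_on_noiseless_expanded_repeats(expanded_points):
    rng = np.random.default_rng(1)
    reps = 12
    X = np.repeat([expanded_points[i] for i in range(1, 9)], reps, axis=0)
    X = X + rng.normal(0, 1e-6, X.shape)  # break exact ties only
    v = np.repeat(np.arange(1, 9), reps)
    lr = feature_partition("LR")
    y = np.array([lr.label_of(i) for i in v])
    assert svm_separable(X, y, conditions=v, rng=rng).separable


def test_svm_criterion_rejects_shuffled_labels():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((8 * 30, 10))
    v = np.repeat(np.arange(8), 30)
    y = rng.choice([-1, 1], X.shape[0])
    # noise-only features with random labels sit at chance
    assert not svm_separable(X, y, conditions=v, rng=rng).separable


def test_svm_criterion_input_validation():
    X = np.random.default_rng(3).standard_normal((20, 4))
    with pytest.raises(ValueError):
        svm_separable(X, np.ones(20), accuracy_threshold=0.4)
    # single-class labeling is trivially separable
    assert svm_separable(X, np.ones(20)).separable


def test_exact_and_svm_agree_on_well_separated_clusters(expanded_points, all_rules):
    """With cluster noise far below the margin the empirical criterion
    reproduces the oracle on every rule, in 3D and 7D."""
    rng = np.random.default_rng(4)
    reps = 8
    for pts in ({i: p[:3] for i, p in expanded_points.items()}, expanded_points):
        P = np.array([pts[i] for i in range(1, 9)])
        X = np.repeat(P, reps, axis=0) + rng.normal(0, 0.01, (8 * reps, P.shape[1]))
        v = np.repeat(np.arange(1, 9), reps)
        for rule in all_rules[::17]:
            y_pts = [rule.label_of(i) for i in range(1, 9)]
            y = np.array([rule.label_of(i) for i in v])
            exact = is_linearly_separable_exact(P, y_pts).separable
            svm = svm_separable(X, y, conditions=v, rng=rng).separable
            assert exact == svm, rule.rule_id
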