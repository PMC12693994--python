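"""Preprocessing, time-binned decoding, baselines, latencies, angles."""

import numpy as np
import pytest

from neurotwist.decoding import (
    DecodingAxis,
    PopulationDataset,
    axis_angle,
    emergence_latency,
    orthogonality_test,
    preprocess,
    shuffle_baseline,
    timebinned_svm,
)
from neurotwist.stimulus_space import ClassificationRule, feature_partition


def test_preprocess_zscores_and_drops_constant_neurons():
    rng = np.random.default_rng(0)
    raw = rng.normal(10.0, 2.0, (4, 200, 6))
    raw[..., 5] = 7.0  # constant neuron
    with pytest.warns(UserWarning, match="constant"):
        data = preprocess(raw)
    assert data.n_neurons == 5
    flat = data.activity.reshape(-1, 5)
    np.testing.assert_allclose(flat.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(flat.std(axis=0), 1.0, atol=1e-9)


def test_preprocess_excludes_sparse_conditions():
    raw = np.random.default_rng(1).normal(size=(5, 50, 3))
    data = preprocess(raw, trial_counts=[5, 2, 3, 0, 7])
    assert data.activity.shape[0] == 3
    np.testing.assert_array_equal(data.condition_vertices, [1, 3, 5])


def test_preprocess_smooths_an_impulse():
    raw = np.zeros((1, 200, 2))
    raw[0, 100, :] = 1.0
    raw[0, :, 1] += np.linspace(0, 1, 200)  # keep nonzero variance shape
    data = preprocess(raw)
    bump = data.activity[0, :, 0]
    peak = np.argmax(bump)
    assert peak == 100
    width = np.sum(bump > bump.max() * 0.5)
    assert 2 <= width <= 12  # ~10 ms at 2-ms steps


def _planted_dataset(rng, n_neurons=40, lags=(40.0, 100.0, 160.0)):
    """Toy data with three planted axes at given lags; each vertex appears
    as three conditions so label shuffles decorrelate from the truth."""
    spec_axes = ["x", "v", "p"]
    t = np.arange(-200.0, 600.0, 2.0)
    from neurotwist.stimulus_space import AXIS_MONOMIALS, CUBE_COORDS

    loads = rng.standard_normal((n_neurons, 3))
    verts = np.tile(np.arange(1, 9), 3)
    raw = np.zeros((verts.size, t.size, n_neurons))
    for ci, v in enumerate(verts):
        for k, (a, lag) in enumerate(zip(spec_axes, lags)):
            mono = np.prod([CUBE_COORDS[v][j] for j in AXIS_MONOMIALS[a]])
            ramp = 1.0 / (1.0 + np.exp(-(t - lag) / 5.0))
            raw[ci] += 3.0 * mono * np.outer(ramp, loads[:, k])
    raw += rng.normal(0, 0.5, raw.shape) + 10.0
    return preprocess(raw, time_ms=t, condition_vertices=verts), spec_axes, lags


def test_planted_axes_decode_above_threshold_and_in_latency_order():
    rng = np.random.default_rng(2)
    data, axes, lags = _planted_dataset(rng)
    latencies = []
    for name in axes:
        rule = feature_partition(name)
        ax = timebinned_svm(data, rule, rng=rng, name=name)
        ax.baseline_band = shuffle_baseline(data, rule, n_shuffles=20, rng=rng)
        steady = ax.accuracy_curve[
            (ax.bin_centers_ms > 250) & (ax.bin_centers_ms < 500)
        ].mean()
        assert steady > 0.75, name
        # pre-onset accuracy stays inside the chance band
        pre = ax.bin_centers_ms < -50
        mean, sd = ax.baseline_band
        assert np.all(ax.accuracy_curve[pre] <= (mean + 3 * sd)[pre] + 0.05)
        lat = emergence_latency(ax)
        assert lat is not None
        latencies.append(lat)
    assert latencies[0] < latencies[1] < latencies[2]


def test_shuffled_labels_stay_at_chance():
    rng = np.random.default_rng(3)
    data, axes, _ = _planted_dataset(rng)
    shuffled = PopulationDataset(
        data.activity, data.time_ms, rng.permutation(data.condition_vertices)
    )
    rule = feature_partition("p")
    ax = timebinned_svm(shuffled, rule, rng=rng)
    mean, sd = shuffle_baseline(data, rule, n_shuffles=25, rng=rng)
    frac_inside = np.mean(ax.accuracy_curve <= mean + 3 * sd)
    assert frac_inside > 0.9


def test_shuffle_baseline_mean_near_chance_for_balanced_rule():
    rng = np.random.default_rng(4)
    data, _, _ = _planted_dataset(rng, n_neurons=20)
    mean, sd = shuffle_baseline(data, feature_partition("x"), n_shuffles=25, rng=rng)
    assert abs(mean.mean() - 0.5) < 0.1
    with pytest.raises(ValueError):
        shuffle_baseline(data, feature_partition("x"), n_shuffles=5, rng=rng)


def test_flat_curve_has_no_latency():
    ax = DecodingAxis(
        "flat",
        np.ones(3) / np.sqrt(3),
        np.arange(-100.0, 500.0, 12.0),
        np.full(50, 0.5),
        baseline_band=(np.full(50, 0.5), np.full(50, 0.02)),
    )
    assert emergence_latency(ax) is None


def test_axis_angle_basics():
    assert axis_angle([1, 0], [1, 0]) == pytest.approx(0.0)
    assert axis_angle([1, 0], [0, 1]) == pytest.approx(90.0)
    with pytest.raises(ValueError):
        axis_angle([0, 0], [1, 0])
    with pytest.raises(ValueError):
        axis_angle([1, 0], [1, 0, 0])


def test_random_93d_angles_concentrate_at_ninety():
    rng = np.random.default_rng(5)
    angles = [
        axis_angle(rng.standard_normal(93), rng.standard_normal(93))
        for _ in range(2000)
    ]
    assert abs(np.mean(angles) - 90.0) < 1.0
    assert abs(np.std(angles) - np.degrees(1 / np.sqrt(93))) < 1.0


def test_orthogonality_test_flags_duplicates_and_accepts_orthogonal():
    rng = np.random.default_rng(6)
    basis = np.linalg.qr(rng.standard_normal((93, 5)))[0].T
    axes = [DecodingAxis(f"a{k}", b, np.array([0.0]), np.array([1.0])) for k, b in enumerate(basis)]
    report = orthogonality_test(axes, rng=rng)
    assert report["mutually_orthogonal"]
    dup = axes + [DecodingAxis("dup", basis[0], np.array([0.0]), np.array([1.0]))]
    report2 = orthogonality_test(dup, rng=rng)
    assert not report2["mutually_orthogonal"]
    assert report2["pairs"][("a0", "dup")]["angle_deg"] == pytest.approx(0.0, abs=1e-9)
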