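"""Time-resolved pseudopopulation decoding.

The pipeline mirrors standard trial-averaged population decoding: firing
rates are smoothed with a 10-ms Gaussian window at a 2-ms step, z-scored
per neuron, and assembled into a conditions × time × neurons tensor.
Linear SVM axes are then trained with a time-bin split: the −200 to
1000 ms range is tiled into 12-ms bins, half the 2-ms time steps inside
every bin train a single classifier and the other half provide a per-bin
held-out accuracy curve.  Chance bands come from condition-label
shuffles (mean ± 3 SD), and an axis' emergence latency is the first
post-onset bin whose accuracy exceeds the band and stays above it for k
consecutive bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.svm import LinearSVC

from .stimulus_space import ClassificationRule

__all__ = [
    "PopulationDataset",
    "DecodingAxis",
    "LatencyReport",
    "preprocess",
    "timebinned_svm",
    "shuffle_baseline",
    "emergence_latency",
    "axis_angle",
    "orthogonality_test",
]

TIME_STEP_MS = 2.0


@dataclass
class PopulationDataset:
    """Trial-averaged, z-scored population activity.

    ``activity`` has shape (n_conditions, n_time, n_neurons); ``time_ms``
    is relative to stimulus onset; ``condition_vertices`` gives the cube
    vertex (1-8) of each condition; optional per-condition coherence
    levels and outcomes carry the full condition table.
    """

    activity: np.ndarray
    time_ms: np.ndarray
    condition_vertices: np.ndarray
    coherence: np.ndarray | None = None
    outcome: np.ndarray | None = None
    #: per-neuron mean/SD applied during z-scoring (None if pre-normalized)
    zscore_mean: np.ndarray | None = None
    zscore_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, float)
        self.time_ms = np.asarray(self.time_ms, float)
        self.condition_vertices = np.asarray(self.condition_vertices, int)
        if self.activity.ndim != 3:
            raise ValueError(f"activity must be 3D, got {self.activity.shape}")
        if self.activity.shape[0] != self.condition_vertices.shape[0]:
            raise ValueError("condition axis mismatch")
        if self.activity.shape[1] != self.time_ms.shape[0]:
            raise ValueError("time axis mismatch")

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[2]


@dataclass
class DecodingAxis:
    """A unit decoding direction with its held-out accuracy time course."""

    name: str
    beta: np.ndarray
    bin_centers_ms: np.ndarray
    accuracy_curve: np.ndarray
    baseline_band: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd) per bin
    latency_ms: float | None = None


@dataclass
class LatencyReport:
    """Axis latencies grouped by twist order, with bootstrap CIs."""

    per_axis: dict[str, float | None]
    category_means: dict[str, float]
    category_cis: dict[str, tuple[float, float]]
    n_bootstrap: int = 100


def preprocess(
    raw_rates,
    time_ms=None,
    condition_vertices=None,
    *,
    window_ms: float = 10.0,
    step_ms: float = TIME_STEP_MS,
    trial_counts=None,
    min_trials: int = 3,
    coherence=None,
    outcome=None,
) -> PopulationDataset:
    """Smooth, z-score, and screen a raw rate tensor.

    Gaussian temporal smoothing (SD = window_ms, sampled at step_ms) is
    followed by per-neuron z-scoring over all retained condition × time
    samples.  Conditions with fewer than ``min_trials`` trials are
    excluded; all-constant neurons (zero variance) are dropped.
    """
    R = np.asarray(raw_rates, float)
    if not np.all(np.isfinite(R)):
        raise ValueError("raw rates must be finite")
    n_cond, n_time, n_neur = R.shape
    if time_ms is None:
        time_ms = -200.0 + step_ms * np.arange(n_time)
    time_ms = np.asarray(time_ms, float)
    if condition_vertices is None:
        condition_vertices = np.arange(1, n_cond + 1)
    condition_vertices = np.asarray(condition_vertices)

    keep_cond = np.ones(n_cond, bool)
    if trial_counts is not None:
        keep_cond = np.asarray(trial_counts) >= min_trials
    R = R[keep_cond]
    condition_vertices = condition_vertices[keep_cond]
    if coherence is not None:
        coherence = np.asarray(coherence)[keep_cond]
    if outcome is not None:
        outcome = np.asarray(outcome)[keep_cond]

    sigma = window_ms / step_ms / 2.0  # 10-ms window ≈ ±1 SD of 5 ms... kernel SD in steps
    smooth = gaussian_filter1d(R, sigma=sigma, axis=1, mode="nearest")

    flat = smooth.reshape(-1, n_neur)
    mu = flat.mean(axis=0)
    sd = flat.std(axis=0)
    keep_neur = sd > 0
    if not keep_neur.all():
        import warnings

        warnings.warn(f"dropping {np.count_nonzero(~keep_neur)} constant neuron(s)")
    z = (smooth[..., keep_neur] - mu[keep_neur]) / sd[keep_neur]
    return PopulationDataset(
        z, time_ms, condition_vertices, coherence, outcome,
        mu[keep_neur], sd[keep_neur],
    )


def _bin_edges(time_ms: np.ndarray, bin_ms: float) -> list[np.ndarray]:
    """Indices of time steps per tiled bin over the full time range."""
    t0 = time_ms[0]
    n_bins = int(np.ceil((time_ms[-1] - t0 + TIME_STEP_MS) / bin_ms))
    bins = []
    for k in range(n_bins):
        lo, hi = t0 + k * bin_ms, t0 + (k + 1) * bin_ms
        idx = np.flatnonzero((time_ms >= lo) & (time_ms < hi))
        # A bin needs at least one train and one test step; a trailing
        # single-step remainder is dropped.
        if idx.size >= 2:
            bins.append(idx)
    return bins


def timebinned_svm(
    data: PopulationDataset,
    rule: ClassificationRule,
    *,
    box_constraint: float = 0.001,
    bin_ms: float = 12.0,
    rng=None,
    name: str | None = None,
) -> DecodingAxis:
    """Train one linear SVM axis with the tiled time-bin split.

    Half the time steps inside every 12-ms bin (chosen at random) train a
    single classifier on pooled (condition, time) samples labeled by the
    rule; the other half yield the per-bin held-out accuracy curve.
    """
    rng = np.random.default_rng(rng)
    labels = np.array([rule.label_of(v) for v in data.condition_vertices])
    if np.unique(labels).size < 2:
        raise ValueError("rule labels only one class on this dataset")
    bins = _bin_edges(data.time_ms, bin_ms)

    train_steps, test_steps = [], []
    for idx in bins:
        perm = rng.permutation(idx)
        half = idx.size // 2
        if half == 0 or idx.size - half == 0:
            raise ValueError("time bin without train or test steps")
        train_steps.append(np.sort(perm[:half]))
        test_steps.append(np.sort(perm[half:]))

    tr = np.concatenate(train_steps)
    Xtr = data.activity[:, tr, :].reshape(-1, data.n_neurons)
    ytr = np.repeat(labels, tr.size)
    # liblinear scales to the tens of thousands of pooled (condition, time)
    # samples typical here; hinge loss keeps the max-margin objective.
    clf = LinearSVC(C=box_constraint, loss="hinge", max_iter=20000)
    clf.fit(Xtr, ytr)

    accs, centers = [], []
    for idx, te in zip(bins, test_steps):
        Xte = data.activity[:, te, :].reshape(-1, data.n_neurons)
        yte = np.repeat(labels, te.size)
        accs.append(float((clf.predict(Xte) == yte).mean()))
        centers.append(float(data.time_ms[idx].mean()))

    beta = clf.coef_.ravel()
    beta = beta / np.linalg.norm(beta)
    return DecodingAxis(name or f"rule{rule.rule_id}", beta, np.array(centers), np.array(accs))


def shuffle_baseline(
    data: PopulationDataset,
    rule: ClassificationRule,
    n_shuffles: int = 100,
    *,
    box_constraint: float = 0.001,
    bin_ms: float = 12.0,
    rng=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Chance-level accuracy band from condition-label permutations.

    Returns pointwise (mean, sd) of the accuracy curve over
    ``n_shuffles`` random permutations of the condition labels; the
    conventional band is mean ± 3 SD.
    """
    if n_shuffles < 20:
        raise ValueError("need at least 20 shuffles for a stable band")
    rng = np.random.default_rng(rng)
    curves = []
    verts = data.condition_vertices.copy()
    for _ in range(n_shuffles):
        shuffled = PopulationDataset(
            data.activity, data.time_ms, rng.permutation(verts),
            data.coherence, data.outcome,
        )
        axis = timebinned_svm(
            shuffled, rule, box_constraint=box_constraint, bin_ms=bin_ms, rng=rng
        )
        curves.append(axis.accuracy_curve)
    curves = np.array(curves)
    return curves.mean(axis=0), curves.std(axis=0)


def emergence_latency(
    axis: DecodingAxis,
    k_consecutive: int = 5,
    *,
    n_sd: float = 3.0,
) -> float | None:
    """First post-onset bin where accuracy clears the chance band and
    stays above it for ``k_consecutive`` bins; None if it never does."""
    if axis.baseline_band is None:
        raise ValueError("axis has no baseline band")
    mean, sd = axis.baseline_band
    above = axis.accuracy_curve > mean + n_sd * sd
    post = axis.bin_centers_ms >= 0
    idx = np.flatnonzero(post)
    for i in idx:
        if i + k_consecutive <= above.size and above[i : i + k_consecutive].all():
            return float(axis.bin_centers_ms[i])
    return None


def axis_angle(beta_i, beta_j) -> float:
    """Angle in degrees between two unit vectors: θ = acos(βᵢᵀβⱼ)."""
    a = np.asarray(beta_i, float).ravel()
    b = np.asarray(beta_j, float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors differ in dimension")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector has no direction")
    return float(np.degrees(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0))))


def orthogonality_test(axes, n_null: int = 200, rng=None) -> dict:
    """Compare observed pairwise angles against the random-vector null.

    The null distribution is the angle between independent uniform random
    unit vectors in the same dimension (concentrated at 90° with SD
    ≈ degrees(1/√n)).  Reports each pair's angle, its z-score under the
    null, and a verdict of mutual orthogonality (all pairs within 3 null
    SDs of 90°).
    """
    axes = list(axes)
    if len(axes) < 2:
        raise ValueError("need at least 2 axes")
    rng = np.random.default_rng(rng)
    dim = np.asarray(axes[0].beta).size
    null = []
    for _ in range(n_null):
        u = rng.standard_normal(dim)
        v = rng.standard_normal(dim)
        null.append(axis_angle(u, v))
    null = np.array(null)
    mu, sd = null.mean(), null.std()

    pairs = {}
    for i in range(len(axes)):
        for j in range(i + 1, len(axes)):
            ang = axis_angle(axes[i].beta, axes[j].beta)
            pairs[(axes[i].name, axes[j].name)] = {
                "angle_deg": ang,
                "z_vs_null": (ang - mu) / sd,
            }
    all_orth = all(abs(p["z_vs_null"]) <= 3.0 for p in pairs.values())
    return {
        "pairs": pairs,
        "null_mean_deg": float(mu),
        "null_sd_deg": float(sd),
        "mutually_orthogonal": bool(all_orth),
    }


def bootstrap_latencies(
    data: PopulationDataset,
    axes_rules: dict[str, ClassificationRule],
    *,
    n_bootstrap: int = 100,
    n_shuffles: int = 30,
    k_consecutive: int = 5,
    box_constraint: float = 0.001,
    rng=None,
) -> LatencyReport:
    """Neuron-level bootstrap of emergence latencies, grouped by twist order.

    Resamples the neuron population with replacement ``n_bootstrap``
    times, re-estimating each axis' latency per resample; reports per-axis
    point estimates (full population), category means over the 0-twist
    (x, y, z), 1-twist (u, v, w), and 2-twist (p) axes, and percentile
    95% CIs of the category means.
    """
    rng = np.random.default_rng(rng)
    category = {"x": "0-twist", "y": "0-twist", "z": "0-twist",
                "u": "1-twist", "v": "1-twist", "w": "1-twist", "p": "2-twist"}

    def run(dataset: PopulationDataset) -> dict[str, float | None]:
        lat = {}
        for name, rule in axes_rules.items():
            ax = timebinned_svm(dataset, rule, box_constraint=box_constraint, rng=rng, name=name)
            ax.baseline_band = shuffle_baseline(
                dataset, rule, n_shuffles=n_shuffles, box_constraint=box_constraint, rng=rng
            )
            lat[name] = emergence_latency(ax, k_consecutive)
        return lat

    point = run(data)
    boot: dict[str, list[float]] = {c: [] for c in ("0-twist", "1-twist", "2-twist")}
    for _ in range(n_bootstrap):
        pick = rng.integers(0, data.n_neurons, data.n_neurons)
        ds = PopulationDataset(
            data.activity[:, :, pick], data.time_ms, data.condition_vertices,
            data.coherence, data.outcome,
        )
        lat = run(ds)
        for c in boot:
            vals = [v for k, v in lat.items() if category.get(k) == c and v is not None]
            if vals:
                boot[c].append(float(np.mean(vals)))

    cat_means, cat_cis = {}, {}
    for c, vals in boot.items():
        if vals:
            arr = np.array(vals)
            cat_means[c] = float(arr.mean())
            cat_cis[c] = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
    return LatencyReport(point, cat_means, cat_cis, n_bootstrap)
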