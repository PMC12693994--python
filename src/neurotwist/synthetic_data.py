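"""Synthetic pseudopopulation generator with planted twist axes.

Stands in for electrophysiological population recordings (none are
bundled): every synthetic neuron carries a nonlinear mix of the
three stimulus features, so the population hosts all seven twist axes
with configurable gains and onset latencies.  Each neuron's rate is

    r(c, t) = baseline
              + Σ_axes gain_a · load_a(neuron) · monomial_a(vertex_c)
                        · ramp(t − latency_a) · coherence_gain(c)
              + noise,

with axis loads drawn with the diversity-d covariance K(d) across
neurons (heterogeneous mixed selectivity) and a logistic ramp (20-ms rise
time) for each axis' emergence.  Default latencies are ordered
0-twist < 1-twist < 2-twist, in the 40-90 ms range typical of mid-level
visual cortex; tests assert recovery of the *planted* values, not any
particular real-data number.

The generator returns the planted ground truth (axis vectors, latencies)
alongside the dataset so the decoding pipeline can be validated by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decoding import PopulationDataset, preprocess
from .stimulus_space import AXIS_MONOMIALS, CUBE_COORDS

__all__ = ["GeneratorSpec", "GroundTruth", "make_trialcounts", "generate"]

_DEFAULT_GAINS = {a: 2.5 for a in AXIS_MONOMIALS}
_DEFAULT_LATENCIES = {
    "x": 45.0, "y": 50.0, "z": 42.0,   # 0-twist
    "u": 65.0, "v": 66.0, "w": 64.0,   # 1-twist
    "p": 86.0,                          # 2-twist
}


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic pseudopopulation."""

    n_neurons: int = 93
    n_coherences: int = 7
    n_outcomes: int = 2
    t_start_ms: float = -200.0
    t_stop_ms: float = 1000.0
    step_ms: float = 2.0
    stim_offset_ms: float = 750.0
    axis_gains: dict = field(default_factory=lambda: dict(_DEFAULT_GAINS))
    axis_latencies_ms: dict = field(default_factory=lambda: dict(_DEFAULT_LATENCIES))
    coherence_gain: tuple | None = None  # per-level manifold-size factor
    baseline: float = 5.0
    noise_sd: float = 0.75
    diversity: float = 1.0
    ramp_rise_ms: float = 20.0
    n_retained_conditions: int = 61
    seed: int | None = None

    def __post_init__(self) -> None:
        lat = self.axis_latencies_ms
        if not (max(lat[a] for a in "xyz")
                <= min(lat[a] for a in "uvw")
                <= max(lat[a] for a in "uvw")
                <= lat["p"]):
            raise ValueError("default latency ordering 0-twist <= 1-twist <= 2-twist violated")
        if self.coherence_gain is None:
            # Larger manifolds at higher coherence.
            self.coherence_gain = tuple(
                0.4 + 0.6 * k / max(1, self.n_coherences - 1)
                for k in range(self.n_coherences)
            )

    def time_axis(self) -> np.ndarray:
        return np.arange(self.t_start_ms, self.t_stop_ms + self.step_ms / 2, self.step_ms)

    def condition_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(vertex, coherence, outcome) per condition, the full factorial."""
        v, c, o = np.meshgrid(
            np.arange(1, 9),
            np.arange(self.n_coherences),
            np.arange(self.n_outcomes),
            indexing="ij",
        )
        return v.ravel(), c.ravel(), o.ravel()


@dataclass
class GroundTruth:
    """Planted structure: per-axis unit load vectors and latencies."""

    axis_vectors: dict[str, np.ndarray]
    axis_latencies_ms: dict[str, float]
    axis_gains: dict[str, float]


def make_trialcounts(spec: GeneratorSpec, rng=None) -> np.ndarray:
    """Per-condition trial counts, with some conditions below threshold.

    Exactly ``n_retained_conditions`` conditions receive >= 3 trials
    (drawn 5-15); the rest get 0-2 trials and exercise the exclusion
    path, mirroring how sparse behavioral sampling prunes a full
    factorial design down to the retained set.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    n_cond = 8 * spec.n_coherences * spec.n_outcomes
    if not 0 <= spec.n_retained_conditions <= n_cond:
        raise ValueError("n_retained_conditions out of range")
    counts = np.zeros(n_cond, dtype=int)
    keep = rng.choice(n_cond, size=spec.n_retained_conditions, replace=False)
    counts[keep] = rng.integers(5, 16, size=keep.size)
    rest = np.setdiff1d(np.arange(n_cond), keep)
    counts[rest] = rng.integers(0, 3, size=rest.size)
    return counts


def _logistic_ramp(t_ms: np.ndarray, latency_ms: float, rise_ms: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t_ms - latency_ms) / (rise_ms / 4.0)))


def generate(spec: GeneratorSpec, rng=None) -> tuple[PopulationDataset, GroundTruth]:
    """Generate a preprocessed dataset plus its planted ground truth.

    Raw rates are simulated per condition (vertex × coherence × outcome),
    trial-count screened, Gaussian-smoothed and z-scored via
    :func:`neurotwist.decoding.preprocess`.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    t = spec.time_axis()
    verts, cohs, outs = spec.condition_table()
    counts = make_trialcounts(spec, rng)

    n = spec.n_neurons
    d = spec.diversity
    # Loads with covariance K(d) across neurons, one draw per axis.
    shared = rng.standard_normal(len(AXIS_MONOMIALS))
    indep = rng.standard_normal((n, len(AXIS_MONOMIALS)))
    loads = np.sqrt(1.0 - d) * shared + np.sqrt(d) * indep

    axis_names = list(AXIS_MONOMIALS)
    mono = np.array(
        [
            [np.prod([CUBE_COORDS[v][j] for j in AXIS_MONOMIALS[a]]) for a in axis_names]
            for v in range(1, 9)
        ],
        dtype=float,
    )  # 8 x 7

    gains = np.array([spec.axis_gains.get(a, 0.0) for a in axis_names])
    # Logistic rise at each axis' latency, decaying back to baseline
    # shortly after stimulus offset.
    off = _logistic_ramp(t, spec.stim_offset_ms + 40.0, spec.ramp_rise_ms)
    ramps = np.array(
        [
            _logistic_ramp(t, spec.axis_latencies_ms[a], spec.ramp_rise_ms) * (1.0 - off)
            for a in axis_names
        ]
    )  # 7 x T

    coh_gain = np.asarray(spec.coherence_gain)
    rates = np.empty((len(verts), t.size, n))
    for ci, (v, ch) in enumerate(zip(verts, cohs)):
        # signal(t, neuron) = Σ_a gain_a load_a mono_a(v) ramp_a(t) coh
        sig = np.einsum("a,na,a,at->tn", gains, loads, mono[v - 1], ramps)
        rates[ci] = spec.baseline + coh_gain[ch] * sig
    # Trial-averaged noise: SD shrinks with the (planted) trial count.
    eff = np.maximum(counts, 1)
    noise = rng.standard_normal(rates.shape) * (spec.noise_sd / np.sqrt(eff))[:, None, None]
    rates = rates + noise

    data = preprocess(
        rates,
        time_ms=t,
        condition_vertices=verts,
        trial_counts=counts,
        coherence=cohs,
        outcome=outs,
    )
    # Ground-truth axis directions in the *z-scored* coordinates the
    # decoder sees: each neuron's load is rescaled by its normalization SD.
    sd = data.zscore_sd if data.n_neurons == n else np.ones(n)
    truth = GroundTruth(
        axis_vectors={
            a: (v := loads[:, k] * gains[k] / sd) / np.linalg.norm(v)
            for k, a in enumerate(axis_names)
            if gains[k] != 0
        },
        axis_latencies_ms=dict(spec.axis_latencies_ms),
        axis_gains={a: float(g) for a, g in zip(axis_names, gains)},
    )
    return data, truth
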