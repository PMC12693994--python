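"""Two-layer feedforward network of nonlinear-mixed-selectivity neurons.

Each of the ``n_neurons`` output neurons receives all three stimulus
features through weights ``w_ij`` and responds

    r_i = ReLU(Σ_j w_ij γ_j + b_i) + ε,

with bias ``b_i ~ U(0, 1)`` drawn once per network instance and noise
``ε ~ N(0, σ²)`` drawn independently per neuron and repeat.  The weights
of each feature are drawn jointly across neurons from a zero-mean
multivariate Gaussian whose covariance ``K(d)`` has unit diagonal and
``1 − d`` off-diagonal: the diversity parameter ``d ∈ [0, 1]``
interpolates between identical connection patterns (d = 0, rank-1 weight
matrix) and independent ones (d = 1, full rank).

The noise standard deviation defaults to 1/3.  A pure-selectivity control
network, in which every neuron receives exactly one feature, is provided
for comparison: it can only realize classifications that are already
linearly separable in the raw stimulus space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .separability import separable_rule_ids_3d, svm_separable
from .stimulus_space import CUBE_COORDS, enumerate_rules

__all__ = [
    "NetworkSpec",
    "ActivationTensor",
    "sample_weights",
    "sample_biases",
    "activate",
    "simulate_network",
    "pure_selectivity_network",
    "pca_variance_spectrum",
    "classification_capacity",
]

DEFAULT_NOISE_SD = 1.0 / 3.0


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of one network instance."""

    n_neurons: int = 93
    d: float = 1.0
    noise_sd: float = DEFAULT_NOISE_SD
    n_repeats: int = 100
    seed: int | None = None
    input_coding: str = "pm1"  # "pm1" (±1 cube) or "01"

    def __post_init__(self) -> None:
        if not 0.0 <= self.d <= 1.0:
            raise ValueError(f"diversity d must be in [0, 1], got {self.d}")
        if self.n_neurons < 1:
            raise ValueError("need at least one neuron")
        if self.input_coding not in ("pm1", "01"):
            raise ValueError(f"unknown input coding {self.input_coding!r}")

    def stimuli(self) -> np.ndarray:
        """The 8 input vectors (vertex order 1-8), shape (8, 3)."""
        V = np.array([CUBE_COORDS[i] for i in range(1, 9)], dtype=float)
        return (V + 1.0) / 2.0 if self.input_coding == "01" else V


@dataclass
class ActivationTensor:
    """Network activity, shape (n_stimuli, n_repeats, n_neurons)."""

    values: np.ndarray
    vertex_indices: tuple[int, ...] = tuple(range(1, 9))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D tensor, got shape {self.values.shape}")
        if self.values.shape[0] != len(self.vertex_indices):
            raise ValueError("stimulus axis does not match vertex_indices")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite activations")

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.values.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[2]

    def condition_means(self) -> np.ndarray:
        """Stimulus-conditioned mean activity, shape (n_stimuli, n_neurons)."""
        return self.values.mean(axis=1)

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """(samples × neurons matrix, vertex index per sample)."""
        X = self.values.reshape(-1, self.n_neurons)
        v = np.repeat(self.vertex_indices, self.n_repeats)
        return X, v


def _weight_covariance(n: int, d: float) -> np.ndarray:
    K = np.full((n, n), 1.0 - d)
    np.fill_diagonal(K, 1.0)
    return K


def sample_weights(spec: NetworkSpec, rng=None) -> np.ndarray:
    """Draw the (n_neurons × 3) weight matrix with covariance K(d).

    Each feature's weight vector is drawn independently from
    ``N(0, K(d))`` across neurons (marginal variance 1 per weight).  The
    degenerate d = 0 covariance (the all-ones matrix) is sampled through
    its exact rank-1 factorization: one shared draw per feature.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    n, d = spec.n_neurons, spec.d
    if d == 0.0:
        return np.tile(rng.standard_normal(3), (n, 1))
    # K(d) = d·I + (1−d)·11ᵀ has exact factor L with L Lᵀ = K:
    # shared component √(1−d) plus independent component √d.
    shared = rng.standard_normal(3)
    indep = rng.standard_normal((n, 3))
    return np.sqrt(1.0 - d) * shared + np.sqrt(d) * indep


def sample_biases(spec: NetworkSpec, rng=None) -> np.ndarray:
    """One bias per neuron, b_i ~ U(0, 1), fixed across repeats."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    return rng.uniform(0.0, 1.0, spec.n_neurons)


def activate(spec: NetworkSpec, weights, biases, stimuli=None, rng=None) -> ActivationTensor:
    """Run the network: ReLU(W γ + b) + noise, per stimulus and repeat."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    W = np.asarray(weights, dtype=float)
    b = np.asarray(biases, dtype=float)
    if W.shape != (spec.n_neurons, 3):
        raise ValueError(f"weights must be ({spec.n_neurons}, 3), got {W.shape}")
    S = spec.stimuli() if stimuli is None else np.asarray(stimuli, dtype=float)
    clean = np.maximum(S @ W.T + b, 0.0)  # (n_stimuli, n_neurons)
    noise = rng.normal(0.0, spec.noise_sd, (S.shape[0], spec.n_repeats, spec.n_neurons))
    values = clean[:, None, :] + noise
    idx = tuple(range(1, S.shape[0] + 1)) if S.shape[0] == 8 else tuple(range(1, S.shape[0] + 1))
    return ActivationTensor(values, idx)


def simulate_network(spec: NetworkSpec, rng=None) -> ActivationTensor:
    """Sample weights and biases, then activate on the 8 cube stimuli."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    W = sample_weights(spec, rng)
    b = sample_biases(spec, rng)
    return activate(spec, W, b, rng=rng)


def pure_selectivity_network(spec: NetworkSpec, rng=None, assignment: str = "round_robin") -> np.ndarray:
    """Weights for the pure-selectivity control: one feature per neuron.

    The nonzero entries within each feature group keep the K(d) covariance
    structure.  ``assignment`` is "round_robin" (balanced 31/31/31 at 93
    neurons) or "random".
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    full = sample_weights(spec, rng)
    n = spec.n_neurons
    if assignment == "round_robin":
        feature = np.arange(n) % 3
    elif assignment == "random":
        feature = rng.integers(0, 3, n)
    else:
        raise ValueError(f"unknown assignment {assignment!r}")
    W = np.zeros_like(full)
    W[np.arange(n), feature] = full[np.arange(n), feature]
    return W


def pca_variance_spectrum(acts: ActivationTensor, on: str = "means", center: bool = True) -> np.ndarray:
    """Fractions of activation variance per principal component.

    ``on="means"`` (default) analyses the 8 stimulus-conditioned mean
    activations; ``on="samples"`` uses every repeat sample.  Fractions are
    non-increasing and sum to 1.
    """
    if on == "means":
        X = acts.condition_means()
    elif on == "samples":
        X, _ = acts.flatten()
    else:
        raise ValueError(f"unknown PCA input {on!r}")
    if center:
        X = X - X.mean(axis=0)
    if np.allclose(X, 0.0):
        raise ValueError("degenerate all-constant input")
    s = np.linalg.svd(X, compute_uv=False)
    ev = s**2
    return ev / ev.sum()


def classification_capacity(
    acts: ActivationTensor,
    rules=None,
    *,
    accuracy_threshold: float = 0.75,
    box_constraint: float = 1.0,
    rng=None,
    separable_ids: frozenset[int] | None = None,
) -> tuple[int, int]:
    """Count dichotomies solved by the held-out linear-SVM criterion.

    Returns ``(n_separable_solved, n_inseparable_solved)`` partitioned by
    each rule's exact-oracle separability in the raw 3D stimulus space.
    The two single-class rules count as solved (a constant classifier is
    perfect on them).
    """
    rng = np.random.default_rng(rng)
    if rules is None:
        rules = enumerate_rules()
    if separable_ids is None:
        separable_ids = separable_rule_ids_3d()
    X, v = acts.flatten()
    n_sep = n_insep = 0
    for rule in rules:
        if rule.is_trivial:
            solved = True
        else:
            y = np.array([rule.label_of(i) for i in v])
            solved = svm_separable(
                X,
                y,
                conditions=v,
                box_constraint=box_constraint,
                accuracy_threshold=accuracy_threshold,
                rng=rng,
                rule_id=rule.rule_id,
            ).separable
        if solved:
            if rule.rule_id in separable_ids:
                n_sep += 1
            else:
                n_insep += 1
    return n_sep, n_insep
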