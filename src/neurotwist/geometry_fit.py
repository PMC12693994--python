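"""Geometry utilities: RC low-pass filter, orthonormal frames, cluster
centers, and affine fits of the theoretical twist manifold to data.

The discrete-time RC low-pass filter is the exponentially weighted moving
average

    x̄(t) = α·x(t) + (1 − α)·x̄(t − 1),    α = 2πΔt f_c / (2πΔt f_c + 1),

applied within a sliding window starting N steps back; it is used only for
visualization-grade smoothing, never inside quantitative statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AffineFit",
    "smoothing_factor",
    "lowpass_filter",
    "orthonormal_frame",
    "steady_state_centers",
    "fit_affine",
]


@dataclass(frozen=True)
class AffineFit:
    """Least-squares affine map ŷ = F x + e with its goodness of fit."""

    F: np.ndarray
    e: np.ndarray
    r_squared: float
    r_squared_per_coordinate: tuple[float, ...]

    def apply(self, x) -> np.ndarray:
        return np.atleast_2d(np.asarray(x, float)) @ self.F.T + self.e


def smoothing_factor(dt_s: float, fc_hz: float) -> float:
    """EWMA smoothing factor α = 2πΔt·f_c / (2πΔt·f_c + 1)."""
    if dt_s <= 0 or fc_hz <= 0:
        raise ValueError("dt_s and fc_hz must be positive")
    w = 2.0 * np.pi * dt_s * fc_hz
    return w / (w + 1.0)


def lowpass_filter(signal, dt_s: float = 0.002, fc_hz: float = 2.0, window_n: int = 5):
    """RC low-pass filter a time series (last axis = time).

    For each output time t the EWMA recursion is restarted ``window_n``
    steps back, so the filter is causal with a finite memory of
    ``window_n`` samples.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    alpha = smoothing_factor(dt_s, fc_hz)
    T = x.shape[-1]
    out = np.empty_like(x)
    for t in range(T):
        start = max(0, t - window_n)
        acc = x[..., start]
        for s in range(start + 1, t + 1):
            acc = alpha * x[..., s] + (1.0 - alpha) * acc
        out[..., t] = acc
    return out


def orthonormal_frame(axes, dim: int | None = None, rng=None) -> np.ndarray:
    """Orthogonal transform whose first rows span the given axes.

    Builds a full-rank matrix whose leading columns are the (unit) input
    axes, QR-decomposes it, and returns ``T = Qᵀ``; projecting data with
    ``T`` puts the input-axis subspace in the first coordinates while the
    remaining rows complete an orthonormal basis.
    """
    A = np.atleast_2d(np.asarray(axes, dtype=float)).T  # dim x k
    n, k = A.shape
    if dim is not None and dim != n:
        raise ValueError(f"axes have dimension {n}, expected {dim}")
    rng = np.random.default_rng(rng)
    rest = rng.standard_normal((n, n - k))
    Q, R = np.linalg.qr(np.hstack([A, rest]))
    diag = np.abs(np.diag(R)[:k])
    if np.any(diag < 1e-10 * max(1.0, np.abs(A).max())):
        bad = int(np.argmin(diag))
        raise ValueError(f"axes are linearly dependent (axis {bad} lies in the span of axes 0..{bad - 1})")
    # Fix signs so the first k rows point along the input axes.
    signs = np.sign(np.diag(R)[:k])
    Q[:, :k] *= signs
    return Q.T


def steady_state_centers(data, window_ms: tuple[float, float] = (200.0, 500.0)) -> np.ndarray:
    """Per-vertex mean population state over a steady-phase time window.

    ``data`` is a :class:`~neurotwist.decoding.PopulationDataset`; returns
    an (8 × n_neurons) array of cluster centers (vertex order 1-8), with
    conditions belonging to the same vertex averaged together.
    """
    lo, hi = window_ms
    mask = (data.time_ms >= lo) & (data.time_ms <= hi)
    if not mask.any():
        raise ValueError(f"window {window_ms} outside time axis")
    verts = np.asarray(data.condition_vertices)
    centers = []
    for vi in range(1, 9):
        sel = verts == vi
        if not sel.any():
            raise ValueError(f"no condition for vertex {vi}")
        centers.append(data.activity[sel][:, mask].mean(axis=(0, 1)))
    return np.array(centers)


def fit_affine(theoretical_points, empirical_points) -> AffineFit:
    """Least-squares affine fit of theoretical 3D points to empirical ones.

    Solves ``ŷ = F x + e`` for F (3×3) and e minimizing the squared
    residuals over matched point pairs; R² is 1 − SS_res/SS_tot, pooled
    over coordinates (per-coordinate values are also reported).
    """
    X = np.atleast_2d(np.asarray(theoretical_points, float))
    Y = np.atleast_2d(np.asarray(empirical_points, float))
    if X.shape != Y.shape:
        raise ValueError(f"point sets differ in shape: {X.shape} vs {Y.shape}")
    n, d = X.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} matched points, got {n}")
    A = np.hstack([X, np.ones((n, 1))])
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    F = coef[:d].T
    e = coef[d]
    resid = Y - (X @ F.T + e)
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per = 1.0 - ss_res / ss_tot
    pooled = 1.0 - ss_res.sum() / ss_tot.sum()
    return AffineFit(F, e, float(pooled), tuple(float(r) for r in per))
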