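"""Linear separability: an exact LP oracle and an empirical SVM criterion.

Two routes are provided and kept deliberately independent:

* :func:`is_linearly_separable_exact` decides *strict* affine separability
  of a finite labeled point set by linear-programming feasibility with a
  unit margin (scale-invariance of the separator makes "strict" and
  "margin ≥ 1" equivalent for finite sets).
* :func:`svm_separable` applies the empirical criterion used on noisy
  population data: train a linear max-margin classifier on half the
  repeats and require held-out accuracy of at least 75% within every
  stimulus condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from sklearn.svm import SVC

from .stimulus_space import ClassificationRule

__all__ = [
    "SeparabilityResult",
    "is_linearly_separable_exact",
    "count_separable_rules",
    "svm_separable",
]

_LP_TOL = 1e-9


@dataclass(frozen=True)
class SeparabilityResult:
    """Outcome of a separability test for one labeling."""

    separable: bool
    method: str  # "exact_oracle" or "svm_75"
    rule_id: int | None = None
    witness_normal: np.ndarray | None = None
    witness_offset: float | None = None
    accuracy_per_condition: dict | None = None

    def __bool__(self) -> bool:  # allows `if result:`
        return self.separable


def is_linearly_separable_exact(points, labels, rule_id: int | None = None) -> SeparabilityResult:
    """Decide strict linear separability of labeled points exactly.

    Searches for (w, b) with ``label · (w·p + b) ≥ 1`` for every point p,
    via LP feasibility.  Single-class inputs are separable by convention
    (any constant classifier is perfect).

    Parameters
    ----------
    points : array-like, shape (n_points, dim)
    labels : array-like of ±1, shape (n_points,)
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    y = np.asarray(labels, dtype=float).ravel()
    if P.size == 0:
        raise ValueError("empty point set")
    if P.shape[0] != y.shape[0]:
        raise ValueError(f"{P.shape[0]} points but {y.shape[0]} labels")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be ±1")

    if np.unique(y).size < 2:
        w = np.zeros(P.shape[1])
        return SeparabilityResult(True, "exact_oracle", rule_id, w, float(y[0]))

    # Feasibility LP: variables (w, b); constraints -y(w·p + b) <= -1.
    n, d = P.shape
    A_ub = -y[:, None] * np.hstack([P, np.ones((n, 1))])
    res = linprog(
        c=np.zeros(d + 1),
        A_ub=A_ub,
        b_ub=-np.ones(n),
        bounds=[(None, None)] * (d + 1),
        method="highs",
    )
    if res.status == 0:
        w, b = res.x[:d], float(res.x[d])
        margins = y * (P @ w + b)
        assert np.all(margins >= 1.0 - _LP_TOL * max(1.0, np.abs(res.x).max()))
        return SeparabilityResult(True, "exact_oracle", rule_id, w, b)
    return SeparabilityResult(False, "exact_oracle", rule_id)


def count_separable_rules(points_by_vertex: dict, rules) -> tuple[int, int]:
    """Count rules separable / inseparable on the given vertex embedding.

    ``points_by_vertex`` maps vertex index (1-8) to its embedded
    coordinates (any dimension).  Returns ``(n_separable, n_inseparable)``
    summing to ``len(rules)``.
    """
    missing = [i for i in range(1, 9) if i not in points_by_vertex]
    if missing:
        raise ValueError(f"missing vertices: {missing}")
    order = sorted(points_by_vertex)
    P = np.asarray([points_by_vertex[i] for i in order], dtype=float)
    n_sep = 0
    for rule in rules:
        y = [rule.label_of(i) for i in order]
        if is_linearly_separable_exact(P, y, rule.rule_id).separable:
            n_sep += 1
    return n_sep, len(rules) - n_sep


def separable_rule_ids_3d() -> frozenset[int]:
    """rule_ids of the dichotomies separable in the raw 3D stimulus cube."""
    from .stimulus_space import CUBE_COORDS, enumerate_rules

    pts = {i: np.array(c, float) for i, c in CUBE_COORDS.items()}
    ids = []
    for rule in enumerate_rules():
        y = [rule.label_of(i) for i in sorted(pts)]
        P = np.array([pts[i] for i in sorted(pts)])
        if is_linearly_separable_exact(P, y).separable:
            ids.append(rule.rule_id)
    return frozenset(ids)


def svm_separable(
    X,
    labels,
    conditions=None,
    *,
    box_constraint: float = 1.0,
    accuracy_threshold: float = 0.75,
    rng=None,
    per_condition: bool = True,
    rule_id: int | None = None,
) -> SeparabilityResult:
    """Empirical separability by the held-out linear-SVM criterion.

    Repeats are split in half (stratified by condition when conditions are
    given); a linear SVM with the given box constraint is trained on one
    half and evaluated on the other.  With ``per_condition=True`` (the
    default) *every* stimulus condition must reach the accuracy threshold
    on held-out samples; otherwise the pooled accuracy is thresholded.

    Single-class labelings are separable by convention.
    """
    if not 0.5 < accuracy_threshold <= 1.0:
        raise ValueError(f"accuracy_threshold must be in (0.5, 1], got {accuracy_threshold}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels).ravel()
    if np.unique(y).size < 2:
        return SeparabilityResult(True, "svm_75", rule_id)
    rng = np.random.default_rng(rng)
    if conditions is None:
        conditions = y
    conditions = np.asarray(conditions).ravel()

    train_idx, test_idx = [], []
    for c in np.unique(conditions):
        idx = np.flatnonzero(conditions == c)
        if idx.size < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        half = idx.size // 2
        train_idx.append(idx[:half])
        test_idx.append(idx[half:])
    train_idx = np.concatenate(train_idx)
    test_idx = np.concatenate(test_idx)

    clf = SVC(kernel="linear", C=box_constraint)
    clf.fit(X[train_idx], y[train_idx])
    pred = clf.predict(X[test_idx])
    correct = pred == y[test_idx]

    acc = {}
    for c in np.unique(conditions):
        mask = conditions[test_idx] == c
        acc[c] = float(correct[mask].mean())
    if per_condition:
        ok = all(a >= accuracy_threshold for a in acc.values())
    else:
        ok = float(correct.mean()) >= accuracy_threshold

    w = clf.coef_.ravel().astype(float)
    norm = np.linalg.norm(w)
    return SeparabilityResult(
        bool(ok),
        "svm_75",
        rule_id,
        w / norm if norm > 0 else w,
        float(clf.intercept_[0]),
        acc,
    )
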