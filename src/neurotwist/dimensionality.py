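"""Dimensionality from binary-classification capacity, and increment curves.

The capacity-based estimator asks, for each condition-subset size
``n ∈ {2..8}``: what fraction of the ``2^n`` binary labelings of ``n``
stimulus conditions is linearly realizable?  Let ``n*`` be the largest
``n`` whose fraction exceeds the criterion (0.8 by default).  Since ``n``
shatterable points in general position span an ``(n − 1)``-dimensional
affine subspace, the inferred dimensionality is ``n* − 1`` (a single
condition is always trivially labeled, so the floor is 0).  A
``convention="count"`` switch reports ``n*`` itself instead.

Realizability is judged either by the exact LP oracle (noiseless point
sets) or by the held-out 75%-per-condition linear-SVM criterion (noisy
repeat-structured activations).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .nms_network import ActivationTensor
from .separability import is_linearly_separable_exact, svm_separable
from .stimulus_space import enumerate_rules

__all__ = [
    "DimensionalityReport",
    "infer_dimensionality",
    "population_increment_curve",
]


@dataclass(frozen=True)
class DimensionalityReport:
    """Per-n separable-labeling fractions and the inferred dimensionality."""

    per_n_ratio: dict[int, float]
    inferred_dim: int
    criterion: float = 0.8
    convention: str = "span"


def _iter_labelings(n: int):
    """Nontrivial labelings of n items, one per complement pair.

    Fixes item 0 in the negative class; the complement of each yielded
    labeling has identical separability status, and the two single-class
    labelings are counted separately as trivially separable.
    """
    for m in range(1, 2 ** (n - 1)):
        yield tuple(1 if (m >> k) & 1 else -1 for k in range(n))


def infer_dimensionality(
    data,
    threshold: float = 0.8,
    *,
    method: str | None = None,
    rng=None,
    box_constraint: float = 1.0,
    accuracy_threshold: float = 0.75,
    max_labelings_per_n: int | None = None,
    convention: str = "span",
    stop_at_first_pass: bool = True,
) -> DimensionalityReport:
    """Estimate representational dimensionality from labeling capacity.

    Parameters
    ----------
    data : ActivationTensor or mapping vertex -> point
        Noisy activations (judged with the SVM criterion) or noiseless
        points (judged with the exact oracle).
    threshold : float
        Ratio criterion; the largest passing subset size determines the
        dimensionality.
    max_labelings_per_n : int, optional
        Cap on the number of (subset, labeling) pairs evaluated per n,
        sampled uniformly without replacement; exhaustive when None.
    stop_at_first_pass : bool
        Scan n downward from 8 and stop at the first passing size (the
        ratio is monotone in practice); ratios for smaller n are then not
        evaluated.
    """
    rng = np.random.default_rng(rng)
    if convention not in ("span", "count"):
        raise ValueError(f"unknown convention {convention!r}")

    if isinstance(data, ActivationTensor):
        method = method or "svm"
        n_cond = data.n_stimuli
        X, v = data.flatten()
        vertex_ids = list(data.vertex_indices)

        def is_sep(subset, labeling) -> bool:
            sel = np.isin(v, [vertex_ids[i] for i in subset])
            lab = dict(zip(subset, labeling))
            y = np.array([lab[vertex_ids.index(i)] for i in v[sel]])
            return svm_separable(
                X[sel], y, conditions=v[sel],
                box_constraint=box_constraint,
                accuracy_threshold=accuracy_threshold,
                rng=rng,
            ).separable
    else:
        method = method or "exact"
        points = {k: np.asarray(p, float) for k, p in dict(data).items()}
        vertex_ids = sorted(points)
        n_cond = len(vertex_ids)
        P = np.array([points[i] for i in vertex_ids])

        def is_sep(subset, labeling) -> bool:
            return is_linearly_separable_exact(P[list(subset)], labeling).separable

    if n_cond < 2:
        raise ValueError("need at least 2 stimulus conditions")

    per_n_ratio: dict[int, float] = {}
    n_star = 1  # a single condition is always trivially labeled
    for n in range(n_cond, 1, -1):
        pairs = [
            (sub, lab)
            for sub in itertools.combinations(range(n_cond), n)
            for lab in _iter_labelings(n)
        ]
        if max_labelings_per_n is not None and len(pairs) > max_labelings_per_n:
            keep = rng.choice(len(pairs), size=max_labelings_per_n, replace=False)
            pairs = [pairs[k] for k in keep]
        n_pass = sum(is_sep(sub, lab) for sub, lab in pairs)
        # Each evaluated labeling stands for itself and its complement, and
        # every subset contributes 2 trivially separable single-class
        # labelings out of its 2^n; c_eff rescales when pairs are sampled.
        c_eff = len(pairs) / (2 ** (n - 1) - 1)
        ratio = (2 * n_pass + 2 * c_eff) / (2**n * c_eff)
        per_n_ratio[n] = ratio
        if ratio > threshold:
            n_star = max(n_star, n)
            if stop_at_first_pass:
                break

    dim = n_star - 1 if convention == "span" else (n_star if n_star > 1 else 1)
    return DimensionalityReport(per_n_ratio, dim, threshold, convention)


def population_increment_curve(
    acts: ActivationTensor,
    rules=None,
    *,
    n_repeats_svm: int = 10,
    rng=None,
    sizes=None,
    box_constraint: float = 1.0,
    accuracy_threshold: float = 0.75,
    separable_ids=None,
) -> dict[int, float]:
    """Solved-classification counts as the population grows neuron by neuron.

    Neurons are inserted in a seeded random order; at each population size
    the number of rules passing the SVM criterion is averaged over
    ``n_repeats_svm`` train/test splits.  Returns size -> mean count.
    """
    rng = np.random.default_rng(rng)
    if rules is None:
        rules = enumerate_rules()
    order = rng.permutation(acts.n_neurons)
    if sizes is None:
        sizes = range(1, acts.n_neurons + 1)
    X_full, v = acts.flatten()

    curve: dict[int, float] = {}
    for size in sizes:
        pool = order[:size]
        X = X_full[:, pool]
        counts = []
        for _ in range(n_repeats_svm):
            n_solved = 0
            for rule in rules:
                if rule.is_trivial:
                    n_solved += 1
                    continue
                y = np.array([rule.label_of(i) for i in v])
                if svm_separable(
                    X, y, conditions=v,
                    box_constraint=box_constraint,
                    accuracy_threshold=accuracy_threshold,
                    rng=rng,
                ).separable:
                    n_solved += 1
            counts.append(n_solved)
        curve[int(size)] = float(np.mean(counts))
    return curve
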