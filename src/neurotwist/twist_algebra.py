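"""The double-twist feature expansion and its subspace combinatorics.

A "twist" bends and rotates a feature sheet so that a planar XOR becomes
linearly separable; algebraically it multiplies two coordinates.  Applying
all twists to the 3D stimulus coordinates (x, y, z) yields the 7D
perceptual coordinates

    (x, y, z, u, w, v, p) = (x, y, z, x·y, y·z, z·x, x·y·z),

where u, w, v are the one-twist (quadratic) axes and p the two-twist
(cubic) axis.  On the ±1 cube the expanded vectors, with a constant +1
appended, form 8 mutually orthogonal 8-vectors (a Walsh–Hadamard system),
so *every* dichotomy of the 8 vertices is linearly separable in 7D.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .separability import is_linearly_separable_exact
from .stimulus_space import (
    AXIS_MONOMIALS,
    CUBE_COORDS,
    ClassificationRule,
    enumerate_rules,
    resolve_axis,
)

__all__ = [
    "EXPANDED_AXES",
    "SubspaceWitness",
    "twist_expand",
    "expanded_cube",
    "xor_product_check",
    "enumerate_subspaces",
    "subspace_coverage",
]

#: Axis order of the 7D expansion.
EXPANDED_AXES: tuple[str, ...] = ("x", "y", "z", "u", "w", "v", "p")


@dataclass(frozen=True)
class SubspaceWitness:
    """A 3-axis subspace in which a rule is (or is not) separable."""

    rule_id: int
    axes: tuple[str, str, str]
    separable_in_subspace: bool


def twist_expand(point):
    """Expand 3D point(s) to the 7 twist coordinates (x,y,z,xy,yz,zx,xyz).

    Accepts a single (x, y, z) triple or an (N, 3) array; continuous
    inputs are allowed (the monomials are evaluated as plain products).
    """
    P = np.asarray(point, dtype=float)
    single = P.ndim == 1
    P = np.atleast_2d(P)
    if P.shape[1] != 3:
        raise ValueError(f"expected 3 base coordinates, got shape {P.shape}")
    cols = [np.prod(P[:, list(AXIS_MONOMIALS[a])], axis=1) for a in EXPANDED_AXES]
    out = np.column_stack(cols)
    return out[0] if single else out


def expanded_cube() -> dict[int, np.ndarray]:
    """Vertex index -> 7D twist-expanded coordinates of the ±1 cube."""
    return {i: twist_expand(np.array(c, float)) for i, c in CUBE_COORDS.items()}


def xor_product_check(booleans) -> tuple[bool, int]:
    """XOR of Booleans vs. the product of their ±1 encodings.

    With true ↦ −1 and false ↦ +1, the XOR of any number of Booleans
    decodes from the arithmetic product of their encodings: the product is
    −1 exactly when the XOR is true.  Returns ``(logic_value,
    arithmetic_value)``.
    """
    booleans = list(booleans)
    if not booleans:
        raise ValueError("need at least one Boolean")
    logic = False
    prod = 1
    for b in booleans:
        logic ^= bool(b)
        prod *= -1 if b else 1
    assert (prod == -1) == logic
    return logic, prod


def enumerate_subspaces() -> list[tuple[str, str, str]]:
    """All C(7,3) = 35 three-axis subspaces of the 7D perceptual space."""
    return list(itertools.combinations(EXPANDED_AXES, 3))


def subspace_coverage(rules=None, inseparable_only: bool = True):
    """Witness subspaces for each rule, and a coverage summary.

    For every rule that is inseparable in the raw 3D cube (or every rule,
    with ``inseparable_only=False``), tests exact separability within each
    of the 35 three-axis subspaces of the 7D expansion.

    Returns ``(witnesses, summary)`` where ``witnesses`` maps rule_id to
    the list of separating 3-axis subspaces and ``summary`` reports the
    counts (every 3D-inseparable rule has at least one witness).
    """
    from .separability import separable_rule_ids_3d

    if rules is None:
        rules = enumerate_rules()
    exp = expanded_cube()
    order = sorted(exp)
    E = np.array([exp[i] for i in order])  # 8 x 7
    col = {a: k for k, a in enumerate(EXPANDED_AXES)}
    sep3 = separable_rule_ids_3d()

    subspaces = enumerate_subspaces()
    witnesses: dict[int, list[tuple[str, str, str]]] = {}
    considered = []
    for rule in rules:
        if inseparable_only and rule.rule_id in sep3:
            continue
        considered.append(rule.rule_id)
        y = [rule.label_of(i) for i in order]
        hits = []
        for axes in subspaces:
            sub = E[:, [col[a] for a in axes]]
            if is_linearly_separable_exact(sub, y, rule.rule_id).separable:
                hits.append(axes)
        witnesses[rule.rule_id] = hits

    summary = {
        "n_subspaces": len(subspaces),
        "n_rules_considered": len(considered),
        "n_rules_covered": sum(1 for r in considered if witnesses[r]),
    }
    return witnesses, summary
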