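"""The eight-stimulus cube and its binary classification rules.

Motion-induced-contour stimuli vary along three binary features: the motion
axis (horizontal vs. vertical, HV), the sheared configuration (outward vs.
inward, OI), and the rotation sense (clockwise-like vs. anticlockwise-like,
CA).  The eight stimuli therefore sit at the vertices of a cube in a
three-dimensional feature space.  We encode each feature as ±1 so that
logical XOR corresponds exactly to an arithmetic product of coordinates:
with true ↦ −1 and false ↦ +1, ``X ⊕ Y`` has the same truth table as
``x·y``.

The perceived contour orientation (left- vs. right-tilted, the LR label)
is the three-way XOR of the features — the cubic XOR problem — and is the
sign of the monomial ``x·y·z``.  Vertices are numbered 1–8; the numbering
is fixed uniquely by the three feature partitions:

* HV: ``x = +1`` on {1, 2, 5, 6}
* OI: ``y = +1`` on {1, 3, 5, 7}
* CA: ``z = +1`` on {2, 3, 5, 8}

Right-tilted contours are vertices {1, 2, 3, 4} (``x·y·z = −1``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "StimulusVertex",
    "ClassificationRule",
    "AXIS_MONOMIALS",
    "AXIS_ALIASES",
    "CUBE_COORDS",
    "build_cube",
    "enumerate_rules",
    "feature_partition",
]

# Vertex sets on which each base feature equals +1.
_POSITIVE_MEMBERS = {
    "x": frozenset({1, 2, 5, 6}),  # HV
    "y": frozenset({1, 3, 5, 7}),  # OI
    "z": frozenset({2, 3, 5, 8}),  # CA
}

#: Monomial (tuple of base-coordinate indices) defining each named axis.
AXIS_MONOMIALS: dict[str, tuple[int, ...]] = {
    "x": (0,),
    "y": (1,),
    "z": (2,),
    "u": (0, 1),  # xy
    "w": (1, 2),  # yz
    "v": (2, 0),  # zx
    "p": (0, 1, 2),  # xyz
}

#: Stimulus-feature and task aliases for the named axes.
AXIS_ALIASES: dict[str, str] = {"HV": "x", "OI": "y", "CA": "z", "LR": "p"}

#: Vertex index (1-8) -> (x, y, z) coordinates, derived from the partitions.
CUBE_COORDS: dict[int, tuple[int, int, int]] = {
    i: tuple(1 if i in _POSITIVE_MEMBERS[a] else -1 for a in "xyz")
    for i in range(1, 9)
}


@dataclass(frozen=True)
class StimulusVertex:
    """One of the 8 stimuli, as a point of the ±1 feature cube."""

    index: int
    coords: tuple[int, int, int]
    orientation: str  # "right_tilted" or "left_tilted"

    def __post_init__(self) -> None:
        if self.index not in range(1, 9):
            raise ValueError(f"vertex index must be 1-8, got {self.index}")
        if any(c not in (-1, 1) for c in self.coords):
            raise ValueError(f"coordinates must be ±1, got {self.coords}")


@dataclass(frozen=True)
class ClassificationRule:
    """A binary labeling of the 8 vertices: one of the 256 dichotomies.

    ``rule_id`` is a canonical bit encoding: vertex ``i`` is in the
    positive class iff bit ``i − 1`` of ``rule_id`` is set.
    """

    rule_id: int
    positive_set: frozenset[int] = field(compare=False)

    def __post_init__(self) -> None:
        if not 0 <= self.rule_id <= 255:
            raise ValueError(f"rule_id must be 0-255, got {self.rule_id}")
        expected = sum(1 << (i - 1) for i in self.positive_set)
        if expected != self.rule_id:
            raise ValueError(
                f"rule_id {self.rule_id} inconsistent with positive_set "
                f"{sorted(self.positive_set)}"
            )

    @classmethod
    def from_positive_set(cls, positive: set[int] | frozenset[int]) -> "ClassificationRule":
        positive = frozenset(positive)
        if not positive <= set(range(1, 9)):
            raise ValueError(f"positive_set must be a subset of 1-8: {sorted(positive)}")
        return cls(sum(1 << (i - 1) for i in positive), positive)

    @classmethod
    def from_rule_id(cls, rule_id: int) -> "ClassificationRule":
        return cls(rule_id, frozenset(i for i in range(1, 9) if rule_id >> (i - 1) & 1))

    @property
    def labels(self) -> dict[int, int]:
        """Vertex index -> ±1 label (+1 for the positive class)."""
        return {i: (1 if i in self.positive_set else -1) for i in range(1, 9)}

    def label_of(self, vertex_index: int) -> int:
        return 1 if vertex_index in self.positive_set else -1

    def complement(self) -> "ClassificationRule":
        return ClassificationRule.from_positive_set(
            frozenset(range(1, 9)) - self.positive_set
        )

    @property
    def is_trivial(self) -> bool:
        """True for the single-class dichotomies (empty or full positive set)."""
        return len(self.positive_set) in (0, 8)


def build_cube() -> list[StimulusVertex]:
    """Construct the 8 stimulus vertices of the ±1 feature cube.

    The coordinate signs satisfy the three feature partitions
    simultaneously, and the contour orientation is right-tilted exactly
    when ``x·y·z == −1`` (vertices 1-4).
    """
    vertices = []
    for i in range(1, 9):
        x, y, z = CUBE_COORDS[i]
        orientation = "right_tilted" if x * y * z == -1 else "left_tilted"
        vertices.append(StimulusVertex(i, (x, y, z), orientation))
    return vertices


def enumerate_rules() -> list[ClassificationRule]:
    """All 2^8 = 256 binary classification rules of the 8 stimuli.

    Includes the two single-class rules (empty and full positive set);
    closed under complementation.
    """
    return [ClassificationRule.from_rule_id(m) for m in range(256)]


def resolve_axis(axis: str) -> str:
    """Map an axis name or stimulus-feature alias to its canonical name."""
    name = AXIS_ALIASES.get(axis, axis)
    if name not in AXIS_MONOMIALS:
        raise ValueError(
            f"unknown axis {axis!r}; expected one of "
            f"{sorted(AXIS_MONOMIALS) + sorted(AXIS_ALIASES)}"
        )
    return name


def feature_partition(axis: str) -> ClassificationRule:
    """The vertex partition induced by a named axis.

    The positive class is the side on which the axis' monomial equals +1:
    e.g. ``feature_partition("v")`` gives {2, 4, 5, 7} (``z·x = +1``) and
    ``feature_partition("LR")`` gives the left-tilted set {5, 6, 7, 8}.
    """
    name = resolve_axis(axis)
    monomial = AXIS_MONOMIALS[name]
    positive = frozenset(
        i
        for i, c in CUBE_COORDS.items()
        if _prod(c[j] for j in monomial) == 1
    )
    return ClassificationRule.from_positive_set(positive)


def _prod(values) -> int:
    out = 1
    for v in values:
        out *= v
    return out
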