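"""Reindexing (twin-law) operators and asymmetric-unit canonicalization.

The indexing ambiguity arises when the Bravais lattice of a crystal has
higher symmetry than its space group: auto-indexing from spot positions
alone cannot distinguish two (or more) reindexing-related settings.  This
module represents the candidate reindexing operators (the "modes" among
which the EM detwinner chooses) and maps Miller indices onto a canonical
asymmetric-unit representative so that symmetry-equivalent observations
accumulate in a single model entry.

Conventions
-----------
* Operators are integer 3x3 matrices acting on (h, k, l) column vectors.
* The canonical representative of an orbit is its lexicographically
  greatest (h, k, l) tuple — arbitrary but deterministic; any fixed total
  order would do.
* The default two-mode group for point group 6 (space group P6_3) is
  {identity, (h,k,l) -> (k,h,-l)}, the standard merohedral twin law, which
  reproduces the l = 0 zone equivalence {h,k,0} <-> {k,h,0}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "MillerIndex",
    "ReindexOperator",
    "AmbiguityGroup",
    "PointGroup",
    "apply_operator",
    "asu_map",
    "twin_invariant_mask",
    "validate_group",
    "diagnose_group",
    "IDENTITY",
    "P63_TWIN",
]


class MillerIndex(NamedTuple):
    """Integer reciprocal-lattice coordinates of a Bragg reflection."""

    h: int
    k: int
    l: int


def _as_matrix(m) -> np.ndarray:
    a = np.asarray(m, dtype=np.int64)
    if a.shape != (3, 3):
        raise ValueError(f"operator matrix must be 3x3, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class ReindexOperator:
    """An integer reindexing operator acting on (h,k,l) column vectors.

    Lattice-preserving operators have determinant +1 or -1; applying one to
    integer indices always yields integer indices.
    """

    matrix: np.ndarray
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "matrix", _as_matrix(self.matrix))
        self.matrix.setflags(write=False)

    @property
    def determinant(self) -> int:
        return int(round(np.linalg.det(self.matrix)))

    def is_identity(self) -> bool:
        return bool(np.array_equal(self.matrix, np.eye(3, dtype=np.int64)))

    def compose(self, other: "ReindexOperator") -> "ReindexOperator":
        """self after other: (self @ other) acting on column vectors."""
        return ReindexOperator(self.matrix @ other.matrix,
                               label=f"{self.label}*{other.label}")

    def __eq__(self, other):
        return isinstance(other, ReindexOperator) and np.array_equal(
            self.matrix, other.matrix)

    def __hash__(self):
        return hash(self.matrix.tobytes())


IDENTITY = ReindexOperator(np.eye(3, dtype=np.int64), label="identity")

#: Merohedral twin law for point group 6: (h,k,l) -> (k,h,-l).
P63_TWIN = ReindexOperator(
    np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]], dtype=np.int64),
    label="twin")


def apply_operator(op: ReindexOperator, hkl) -> np.ndarray | MillerIndex:
    """Apply a reindexing operator to one index or an (N, 3) array of them.

    Returns a :class:`MillerIndex` for a single triple, otherwise an
    integer array of the same shape as the input.
    """
    a = np.asarray(hkl, dtype=np.int64)
    if a.ndim == 1:
        out = op.matrix @ a
        return MillerIndex(int(out[0]), int(out[1]), int(out[2]))
    return a @ op.matrix.T


@dataclass
class AmbiguityGroup:
    """The set of candidate indexing modes among which EM chooses.

    ``operators[0]`` must be the identity.  For the common two-mode
    (twin-like) case the second operator must be an involution.
    """

    operators: list[ReindexOperator] = field(
        default_factory=lambda: [IDENTITY, P63_TWIN])

    @property
    def n_modes(self) -> int:
        return len(self.operators)

    @classmethod
    def p63(cls) -> "AmbiguityGroup":
        """Default group for P6_3: {identity, (h,k,l)->(k,h,-l)}."""
        return cls([IDENTITY, P63_TWIN])

    @classmethod
    def single(cls) -> "AmbiguityGroup":
        """No ambiguity (one mode); EM reduces to plain merging."""
        return cls([IDENTITY])

    def compose_index(self, i: int, j: int) -> int:
        """Index of operators[i] @ operators[j] within the group.

        Raises ValueError if the product is not a group element (the group
        need only be closed for validated two-mode cases).
        """
        prod = self.operators[i].matrix @ self.operators[j].matrix
        for m, op in enumerate(self.operators):
            if np.array_equal(op.matrix, prod):
                return m
        raise ValueError("composition leaves the ambiguity group")


def diagnose_group(g: AmbiguityGroup) -> list[str]:
    """Return a list of problems; empty means the group is usable."""
    problems: list[str] = []
    if not g.operators:
        return ["group has no operators"]
    if not g.operators[0].is_identity():
        problems.append("operators[0] is not the identity")
    for i, op in enumerate(g.operators):
        if op.determinant not in (1, -1):
            problems.append(
                f"operator {i} ({op.label!r}) has determinant "
                f"{op.determinant}, not ±1 (not lattice-preserving)")
    if g.n_modes == 2:
        sq = g.operators[1].matrix @ g.operators[1].matrix
        if not np.array_equal(sq, np.eye(3, dtype=np.int64)):
            problems.append("two-mode group: operators[1] is not an involution")
    return problems


def validate_group(g: AmbiguityGroup) -> bool:
    """True iff the group passes all structural checks (see diagnose_group)."""
    return not diagnose_group(g)


def _closed_under_composition(mats: Sequence[np.ndarray]) -> bool:
    keys = {m.tobytes() for m in mats}
    return all((a @ b).astype(np.int64).tobytes() in keys
               for a in mats for b in mats)


@dataclass
class PointGroup:
    """Proper rotations of the merging point group, plus Friedel pairing.

    Used only to canonicalize Miller indices so that multiple measurements
    of the same Bragg spot land in one accumulator; this is deliberately
    not general space-group machinery.
    """

    operators: list[np.ndarray]
    include_friedel: bool = True

    def __post_init__(self):
        self.operators = [_as_matrix(m) for m in self.operators]
        if not any(np.array_equal(m, np.eye(3, dtype=np.int64))
                   for m in self.operators):
            raise ValueError("point group must contain the identity")
        if not _closed_under_composition(self.operators):
            raise ValueError("point group is not closed under composition")

    @classmethod
    def identity_only(cls, friedel: bool = True) -> "PointGroup":
        return cls([np.eye(3, dtype=np.int64)], include_friedel=friedel)

    @classmethod
    def hexagonal_6(cls, friedel: bool = True) -> "PointGroup":
        """Proper point group 6: powers of the hexagonal 6-fold about c.

        The generator acts on reciprocal indices as (h,k,l) -> (-k, h+k, l).
        """
        gen = np.array([[0, -1, 0], [1, 1, 0], [0, 0, 1]], dtype=np.int64)
        ops, m = [], np.eye(3, dtype=np.int64)
        for _ in range(6):
            ops.append(m)
            m = gen @ m
        return cls(ops, include_friedel=friedel)

    @property
    def n_images(self) -> int:
        return len(self.operators) * (2 if self.include_friedel else 1)

    def image_matrices(self) -> list[np.ndarray]:
        mats = list(self.operators)
        if self.include_friedel:
            mats += [-m for m in self.operators]
        return mats


def twin_invariant_mask(indices, op: ReindexOperator,
                        pg: PointGroup) -> np.ndarray:
    """True where a canonical index is fixed by the twin operator.

    A reflection is twin-invariant when the operator maps it into its own
    point-group orbit (e.g. h = k, h = 0 or k = 0 classes for the
    hexagonal (k,h,-l) law).  Mode mixing cannot corrupt these entries,
    so statistics that quantify twin mixing should exclude them.
    """
    a = np.asarray(indices, dtype=np.int64).reshape(-1, 3)
    return (asu_map(apply_operator(op, a), pg) == a).all(axis=1)


def asu_map(hkl, pg: PointGroup):
    """Canonical (asymmetric-unit) representative of an index's orbit.

    The representative is the lexicographically greatest (h, k, l) tuple
    over the point-group orbit (with Friedel mates included when enabled).
    Accepts a single triple (returns :class:`MillerIndex`) or an (N, 3)
    array (returns an (N, 3) array).  (0,0,0) is rejected for single
    triples; array input may contain it only if the caller filters it.
    """
    a = np.asarray(hkl, dtype=np.int64)
    single = a.ndim == 1
    if single:
        if not a.any():
            raise ValueError("(0,0,0) is a degenerate reflection")
        a = a[None, :]
    images = np.stack([a @ m.T for m in pg.image_matrices()])  # (n_img, N, 3)
    # lexicographic argmax over images, per reflection
    best = images[0].copy()
    for img in images[1:]:
        h_gt = img[:, 0] > best[:, 0]
        h_eq = img[:, 0] == best[:, 0]
        k_gt = h_eq & (img[:, 1] > best[:, 1])
        k_eq = h_eq & (img[:, 1] == best[:, 1])
        l_gt = k_eq & (img[:, 2] > best[:, 2])
        take = h_gt | k_gt | l_gt
        best[take] = img[take]
    if single:
        return MillerIndex(int(best[0, 0]), int(best[0, 1]), int(best[0, 2]))
    return best
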