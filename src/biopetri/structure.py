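"""Incidence matrices, state equation, and minimal invariant enumeration.

Matrix orientation
------------------
All matrices here have **rows = transitions, columns = places** (n×m).
Both conventions exist in the literature; this one is fixed throughout
the package and in every serialized artifact.

Invariants
----------
An S-invariant is a semi-positive integer place-weight vector ``Y``
(``Y >= 0``, ``Y != 0``) with ``A·Y = 0``: the Y-weighted token sum is
conserved by every firing.  A T-invariant is a semi-positive
transition-count vector ``X`` with ``Aᵀ·X = 0``: a realizable firing
count vector with those counts reproduces the marking it started from.

Enumeration uses Farkas-style (Martínez–Silva) row elimination on the
tableau ``[A | I]`` with exact integer arithmetic, followed by
minimal-support filtering and gcd normalization.  Output order is
canonical (lexicographic by vector), so results are reproducible across
runs and platforms.

Self-loops: invariants are computed from ``A = A⁺ − A⁻``; when a
(transition, place) pair carries both an input and an output arc the
cancellation loses that information, and report generation attaches a
warning (see :mod:`biopetri.bio_annotation`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import DimensionError, EnumerationSizeError, KindError
from .pn_core import Marking, PetriNetStructure

__all__ = [
    "IncidenceTriple",
    "Invariant",
    "input_matrix",
    "output_matrix",
    "incidence_matrix",
    "apply_firing_count",
    "minimal_s_invariants",
    "minimal_t_invariants",
    "verify_invariant",
    "coverage",
    "brute_force_invariants",
    "write_matrix_tsv",
]

Kind = Literal["S", "T"]

# Guard for brute_force_invariants: cap on the number of candidate
# vectors (max_entry+1)**dimension actually enumerated.
BRUTE_FORCE_MAX_CANDIDATES = 500_000


@dataclass(frozen=True)
class IncidenceTriple:
    """Input matrix A⁻, output matrix A⁺ and incidence matrix A = A⁺ − A⁻."""

    a_minus: np.ndarray
    a_plus: np.ndarray
    a: np.ndarray

    def __post_init__(self):
        if self.a_minus.shape != self.a_plus.shape or self.a.shape != self.a_minus.shape:
            raise DimensionError("incidence matrices must share one shape")
        if (self.a_minus < 0).any() or (self.a_plus < 0).any():
            raise DimensionError("A⁻ and A⁺ must be nonnegative")
        if not np.array_equal(self.a, self.a_plus - self.a_minus):
            raise DimensionError("A must equal A⁺ − A⁻ elementwise")


@dataclass(frozen=True)
class Invariant:
    """A semi-positive integer invariant vector with its support.

    ``kind`` is ``"S"`` (vector over places) or ``"T"`` (over
    transitions).  ``support`` holds the identifiers with positive
    entries; ``normalized`` is True when the gcd of positive entries
    is 1.
    """

    kind: Kind
    vector: tuple[int, ...]
    support: frozenset[str]
    normalized: bool

    def __post_init__(self):
        if self.kind not in ("S", "T"):
            raise KindError(f"invariant kind must be 'S' or 'T', got {self.kind!r}")
        if any(v < 0 for v in self.vector) or not any(self.vector):
            raise DimensionError("invariant vector must be semi-positive (>=0, nonzero)")
        if self.normalized and math.gcd(*(v for v in self.vector if v > 0)) != 1:
            raise DimensionError("normalized invariant must have gcd 1")

    @classmethod
    def from_vector(
        cls, net: PetriNetStructure, kind: Kind, vector: Sequence[int]
    ) -> "Invariant":
        ids = net.places if kind == "S" else net.transitions
        vector = tuple(int(v) for v in vector)
        if len(vector) != len(ids):
            raise DimensionError(
                f"{kind}-invariant vector must have length {len(ids)}, got {len(vector)}"
            )
        positive = [v for v in vector if v > 0]
        return cls(
            kind=kind,
            vector=vector,
            support=frozenset(i for i, v in zip(ids, vector) if v > 0),
            normalized=bool(positive) and math.gcd(*positive) == 1,
        )


def input_matrix(net: PetriNetStructure) -> np.ndarray:
    """A⁻: entry (i, j) is the weight of the arc place sⱼ → transition tᵢ."""
    a = np.zeros((net.n_transitions, net.n_places), dtype=np.int64)
    for (t, p), w in net.pre.items():
        a[net.transition_index(t), net.place_index(p)] = w
    return a


def output_matrix(net: PetriNetStructure) -> np.ndarray:
    """A⁺: entry (i, j) is the weight of the arc transition tᵢ → place sⱼ."""
    a = np.zeros((net.n_transitions, net.n_places), dtype=np.int64)
    for (t, p), w in net.post.items():
        a[net.transition_index(t), net.place_index(p)] = w
    return a


def incidence_matrix(net: PetriNetStructure) -> IncidenceTriple:
    a_minus = input_matrix(net)
    a_plus = output_matrix(net)
    return IncidenceTriple(a_minus=a_minus, a_plus=a_plus, a=a_plus - a_minus)


def apply_firing_count(
    net: PetriNetStructure, m: Marking, x: Sequence[int]
) -> tuple[int, ...]:
    """State equation: return ``m + xᵀ·A`` as a plain integer vector.

    The result may contain negative entries (the firing-count vector
    need not be realizable); callers interpret feasibility.  When ``x``
    counts the firings of an executable sequence from ``m``, the result
    equals that sequence's final marking.
    """
    m = Marking.coerce(m)
    x = np.asarray(list(x), dtype=np.int64)
    if x.shape != (net.n_transitions,):
        raise DimensionError(
            f"firing-count vector must have length {net.n_transitions}"
        )
    result = np.asarray(m.counts, dtype=np.int64) + x @ incidence_matrix(net).a
    return tuple(int(v) for v in result)


# ----------------------------------------------------------------------
# Invariant enumeration
# ----------------------------------------------------------------------


def _normalize(vec: tuple[int, ...]) -> tuple[int, ...]:
    g = math.gcd(*vec)
    return tuple(v // g for v in vec) if g > 1 else vec


def _minimal_support_filter(
    vectors: list[tuple[int, ...]]
) -> list[tuple[int, ...]]:
    """Keep gcd-normalized vectors whose support contains no other
    solution's support strictly; dedupe exact vectors.

    A minimal support determines its normalized solution uniquely, so
    strict-subset filtering plus exact dedup is sufficient.
    """
    normed = sorted({_normalize(v) for v in vectors})
    supports = [frozenset(i for i, x in enumerate(v) if x > 0) for v in normed]
    return [
        v
        for i, v in enumerate(normed)
        if not any(j != i and supports[j] < supports[i] for j in range(len(normed)))
    ]


def _farkas(matrix: np.ndarray) -> list[tuple[int, ...]]:
    """Semi-positive integer solutions ``y`` of ``matrix · y = 0``.

    ``matrix`` is k×d; solutions are d-vectors.  Row elimination on the
    tableau ``[matrixᵀ | I_d]``: each tableau row pairs the constraint
    residual of a candidate with the candidate itself.  Eliminating all
    k constraint columns by nonnegative combinations leaves exactly the
    semi-positive solutions (a superset of the minimal ones).
    """
    k, d = matrix.shape
    rows: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    for j in range(d):
        residual = tuple(int(matrix[i, j]) for i in range(k))
        candidate = tuple(1 if jj == j else 0 for jj in range(d))
        rows.append((residual, candidate))

    for col in range(k):
        keep = [r for r in rows if r[0][col] == 0]
        pos = [r for r in rows if r[0][col] > 0]
        neg = [r for r in rows if r[0][col] < 0]
        combos: dict[tuple[int, ...], tuple[int, ...]] = {
            cand: res for res, cand in keep
        }
        for (res_p, cand_p) in pos:
            for (res_n, cand_n) in neg:
                cp, cn = -res_n[col], res_p[col]
                res = tuple(cp * a + cn * b for a, b in zip(res_p, res_n))
                cand = tuple(cp * a + cn * b for a, b in zip(cand_p, cand_n))
                g = math.gcd(*res, *cand)
                if g > 1:
                    res = tuple(v // g for v in res)
                    cand = tuple(v // g for v in cand)
                combos[cand] = res
        rows = [(res, cand) for cand, res in combos.items()]

    solutions = [cand for res, cand in rows if not any(res) and any(cand)]
    return solutions


def _invariant_system(net: PetriNetStructure, kind: Kind) -> np.ndarray:
    a = incidence_matrix(net).a
    if kind == "S":
        return a  # A·Y = 0, Y over places
    if kind == "T":
        return a.T  # Aᵀ·X = 0, X over transitions
    raise KindError(f"kind must be 'S' or 'T', got {kind!r}")


def _enumerate_minimal(net: PetriNetStructure, kind: Kind) -> list[Invariant]:
    matrix = _invariant_system(net, kind)
    if matrix.shape[1] == 0:
        return []
    vectors = _minimal_support_filter(_farkas(matrix))
    return [Invariant.from_vector(net, kind, v) for v in vectors]


def minimal_s_invariants(net: PetriNetStructure) -> list[Invariant]:
    """All minimal-support, gcd-normalized semi-positive solutions of
    ``A·Y = 0``, sorted lexicographically by vector."""
    return _enumerate_minimal(net, "S")


def minimal_t_invariants(net: PetriNetStructure) -> list[Invariant]:
    """All minimal-support, gcd-normalized semi-positive solutions of
    ``Aᵀ·X = 0``, sorted lexicographically by vector."""
    return _enumerate_minimal(net, "T")


def verify_invariant(net: PetriNetStructure, inv: Invariant) -> bool:
    """Exact integer check of ``A·Y = 0`` (S) or ``Aᵀ·X = 0`` (T)."""
    matrix = _invariant_system(net, inv.kind)
    vec = np.asarray(inv.vector, dtype=np.int64)
    if vec.shape[0] != matrix.shape[1]:
        raise DimensionError(
            f"{inv.kind}-invariant has length {vec.shape[0]}, "
            f"expected {matrix.shape[1]}"
        )
    return not (matrix @ vec).any()


def coverage(net: PetriNetStructure, kind: Kind) -> tuple[bool, set[str]]:
    """Which places (S) or transitions (T) lie in no minimal invariant's
    support.  Returns ``(fully_covered, uncovered_identifiers)``."""
    invariants = _enumerate_minimal(net, kind)
    ids = net.places if kind == "S" else net.transitions
    covered: set[str] = set()
    for inv in invariants:
        covered |= inv.support
    uncovered = set(ids) - covered
    return (not uncovered, uncovered)


def brute_force_invariants(
    net: PetriNetStructure, kind: Kind, max_entry: int
) -> list[Invariant]:
    """Independent oracle: exhaustively enumerate all vectors with
    entries in ``0..max_entry``, keep exact solutions of the homogeneous
    system, filter to minimal support and gcd 1, and sort canonically.

    Guarded: refuses when ``(max_entry+1)**dimension`` exceeds
    ``BRUTE_FORCE_MAX_CANDIDATES``.
    """
    matrix = _invariant_system(net, kind)
    dim = matrix.shape[1]
    if dim == 0:
        return []
    n_candidates = (max_entry + 1) ** dim
    if n_candidates > BRUTE_FORCE_MAX_CANDIDATES:
        raise EnumerationSizeError(
            f"{n_candidates} candidate vectors exceed the guard of "
            f"{BRUTE_FORCE_MAX_CANDIDATES}; use a smaller net or max_entry"
        )
    solutions = [
        v
        for v in itertools.product(range(max_entry + 1), repeat=dim)
        if any(v) and not (matrix @ np.asarray(v, dtype=np.int64)).any()
    ]
    vectors = _minimal_support_filter(solutions)
    return [Invariant.from_vector(net, kind, v) for v in vectors]


def write_matrix_tsv(net: PetriNetStructure, matrix: np.ndarray, path) -> None:
    """Write an n×m matrix as TSV: header row of place ids, first column
    transition ids, integer cells."""
    if matrix.shape != (net.n_transitions, net.n_places):
        raise DimensionError("matrix shape must be (transitions, places)")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["id", *net.places]) + "\n")
        for i, t in enumerate(net.transitions):
            fh.write("\t".join([t, *(str(int(v)) for v in matrix[i])]) + "\n")
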