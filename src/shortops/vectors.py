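"""Vector diagram of a signed permutation.

Each element p_i is assigned a vector of length ||p_i| - i| pointing
toward its target position: right if the element must move right
(|p_i| > i), left if it must move left.  Zero-length vectors are kept
with an explicit polarity (zero+ for p_i = i, zero- for p_i = -i) so
that the subset of negative in-place elements is a direct filter.

Vec(p), the total vector length, drives the 5-approximation for sorting
by short reversals: swapping an m-vector-opposite pair reduces Vec by
exactly 2m, and Vec = 0 exactly when the magnitudes are sorted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .core import Operation, SignedPermutation

__all__ = [
    "Direction",
    "VectorDiagram",
    "VectorSubsetSizes",
    "vector_diagram",
    "vector_subset_sizes",
    "are_vector_opposite",
    "find_vector_opposite_pair",
    "swap_sequence",
]


class Direction(Enum):
    RIGHT = "right"
    LEFT = "left"
    ZERO_POS = "zero+"
    ZERO_NEG = "zero-"


@dataclass(frozen=True)
class VectorDiagram:
    """Per-position vector lengths and directions, plus the total Vec."""

    lengths: tuple[int, ...]
    directions: tuple[Direction, ...]

    @property
    def vec_total(self) -> int:
        return sum(self.lengths)

    def __str__(self) -> str:
        top = " ".join(f"{l:>5d}" for l in self.lengths)
        bot = " ".join(f"{d.value:>5s}" for d in self.directions)
        return f"len: {top}\ndir: {bot}"


@dataclass(frozen=True)
class VectorSubsetSizes:
    """Sizes of the four vector subsets entering the distance bounds.

    even_neg: negative elements with even vector length  (|V^even-|)
    odd_pos:  positive elements with odd vector length   (|V^odd+|)
    odd:      elements with odd vector length            (|V^odd|)
    zero_neg: negative zero vectors, i.e. p_i = -i       (|V^0-|)
    """

    even_neg: int
    odd_pos: int
    odd: int
    zero_neg: int


def vector_diagram(p: SignedPermutation) -> VectorDiagram:
    lengths = []
    directions = []
    for i, e in enumerate(p.elements, start=1):
        delta = abs(e) - i
        lengths.append(abs(delta))
        if delta > 0:
            directions.append(Direction.RIGHT)
        elif delta < 0:
            directions.append(Direction.LEFT)
        elif e > 0:
            directions.append(Direction.ZERO_POS)
        else:
            directions.append(Direction.ZERO_NEG)
    return VectorDiagram(tuple(lengths), tuple(directions))


def vec_total(p: SignedPermutation) -> int:
    """Vec(p): the sum of all vector lengths."""
    return sum(abs(abs(e) - i) for i, e in enumerate(p.elements, start=1))


def vector_subset_sizes(p: SignedPermutation) -> VectorSubsetSizes:
    even_neg = odd_pos = odd = zero_neg = 0
    for i, e in enumerate(p.elements, start=1):
        length = abs(abs(e) - i)
        if length % 2 == 0 and e < 0:
            even_neg += 1
        if length % 2 == 1 and e > 0:
            odd_pos += 1
        if length % 2 == 1:
            odd += 1
        if e == -i:
            zero_neg += 1
    return VectorSubsetSizes(even_neg, odd_pos, odd, zero_neg)


def _direction(p: SignedPermutation, i: int) -> Direction:
    delta = abs(p[i]) - i
    if delta > 0:
        return Direction.RIGHT
    if delta < 0:
        return Direction.LEFT
    return Direction.ZERO_POS if p[i] > 0 else Direction.ZERO_NEG


def are_vector_opposite(p: SignedPermutation, i: int, j: int) -> bool:
    """Whether p_i and p_j are (j-i)-vector-opposite.

    True iff the two vectors point toward each other (right at i, left at
    j) and each is long enough to reach the other's position.  Zero
    vectors have no direction and never qualify.
    """
    if i >= j:
        raise ValueError(f"need i < j, got ({i}, {j})")
    di, dj = _direction(p, i), _direction(p, j)
    if not (di is Direction.RIGHT and dj is Direction.LEFT):
        return False
    m = j - i
    return abs(p[i]) - i >= m and j - abs(p[j]) >= m


def find_vector_opposite_pair(
    p: SignedPermutation,
) -> Optional[tuple[int, int]]:
    """Locate a vector-opposite pair, or None when Vec(p) = 0.

    Procedure: take the rightmost right vector, at position i, with
    target k = |p_i|; select the leftmost left vector at a position j in
    (i, k].  Such a j always exists, and (i, j) is vector-opposite.  One
    refinement: if j = i + 1 but (i, i+2) happens to be 2-vector-opposite,
    return (i, i+2) instead — the returned pair is then adjacent only
    when no 2-vector-opposite pair starts at i, which the short-reversal
    approximation analysis requires.
    """
    i = None
    for pos in range(p.n, 0, -1):
        if abs(p[pos]) - pos > 0:
            i = pos
            break
    if i is None:
        return None  # no right vector -> magnitudes sorted -> Vec = 0
    k = abs(p[i])
    j = None
    for pos in range(i + 1, k + 1):
        if abs(p[pos]) - pos < 0:
            j = pos
            break
    assert j is not None, "a left vector must exist in (i, |p_i|]"
    if j == i + 1 and i + 2 <= p.n and are_vector_opposite(p, i, i + 2):
        return (i, i + 2)
    return (i, j)


def swap_sequence(
    p: SignedPermutation, i: int, j: int
) -> list[Operation]:
    """Short-reversal sequence exchanging the magnitudes at i and j.

    For an m-vector-opposite pair (i, j), m = j - i, returns
    2*ceil(m/2) - 1 short reversals that swap |p_i| and |p_j| while
    leaving every other magnitude in place:

      m even: rho(i,i+2), rho(i+2,i+4), ..., rho(j-2,j),
              rho(j-4,j-2), ..., rho(i,i+2)      (m-1 3-reversals;
              the element ending at j-1 has its sign flipped)
      m odd:  rho(i,i+2), ..., rho(j-3,j-1), rho(j-1,j),
              rho(j-3,j-1), ..., rho(i,i+2)      (m-1 3-reversals and
              one 2-reversal; no other element is disturbed)

    For m = 1 the sequence degenerates to the single 2-reversal
    rho(i, i+1).
    """
    if not are_vector_opposite(p, i, j):
        raise ValueError(f"positions ({i}, {j}) are not vector-opposite in {p}")
    m = j - i
    ops: list[Operation] = []
    if m % 2 == 0:
        up = [Operation.reversal(s, s + 2) for s in range(i, j - 1, 2)]
        down = up[:-1][::-1]
        ops = up + down
    else:
        up = [Operation.reversal(s, s + 2) for s in range(i, j - 2, 2)]
        ops = up + [Operation.reversal(j - 1, j)] + up[::-1]
    assert len(ops) == 2 * ((m + 1) // 2) - 1
    return ops
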