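"""Signed permutations and length-bounded rearrangement operations.

A signed permutation models a unichromosomal gene order: an arrangement of
the integers 1..n in which every element carries an orientation (+ or -).
Sorting a signed permutation into the identity (+1 +2 ... +n) with the
fewest operations gives a rearrangement distance usable as an evolutionary
distance between two genomes.

This module defines the permutation itself, the two operation kinds
(signed reversals and transpositions), the four bounded operation
families, validated sorting scenarios, parsing/formatting, inversion
machinery, and a seeded uniform sampler.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

__all__ = [
    "SignedPermutation",
    "Operation",
    "OperationFamily",
    "SSSR",
    "SSR",
    "SSSO",
    "SSO",
    "FAMILIES",
    "SortingScenario",
    "parse_permutation",
    "parse_operations",
    "identity",
    "apply_operation",
    "inversions",
    "inversion_count",
    "leftmost_adjacent_inversion",
    "enumerate_operations",
    "inverse_operation",
    "random_permutation",
]


class PermutationFormatError(ValueError):
    """Raised when a permutation string or element list is malformed."""


@dataclass(frozen=True)
class SignedPermutation:
    """An ordering of {1, ..., n} in which every element has a sign.

    Immutable: operations return new permutations.  Positions are 1-based
    throughout the public API, matching the genome-rearrangement
    literature.
    """

    elements: tuple[int, ...]

    def __post_init__(self) -> None:
        elems = tuple(int(e) for e in self.elements)
        object.__setattr__(self, "elements", elems)
        n = len(elems)
        if n == 0:
            raise PermutationFormatError("a signed permutation must be non-empty")
        seen: set[int] = set()
        for e in elems:
            if e == 0:
                raise PermutationFormatError("element 0 is not allowed")
            a = abs(e)
            if a in seen:
                raise PermutationFormatError(f"duplicate absolute value {a}")
            seen.add(a)
        if seen != set(range(1, n + 1)):
            missing = sorted(set(range(1, n + 1)) - seen)
            raise PermutationFormatError(
                f"absolute values must be exactly 1..{n}; missing {missing}"
            )

    @property
    def n(self) -> int:
        return len(self.elements)

    def __getitem__(self, pos: int) -> int:
        """Element at 1-based position ``pos``."""
        if not 1 <= pos <= self.n:
            raise IndexError(f"position {pos} out of range 1..{self.n}")
        return self.elements[pos - 1]

    def __iter__(self) -> Iterator[int]:
        return iter(self.elements)

    def __len__(self) -> int:
        return self.n

    def is_identity(self) -> bool:
        return all(e == i for i, e in enumerate(self.elements, start=1))

    def __str__(self) -> str:
        return " ".join(f"{e:+d}" for e in self.elements)

    def __repr__(self) -> str:
        return f"SignedPermutation(({', '.join(f'{e:+d}' for e in self.elements)}))"


@dataclass(frozen=True, order=True)
class Operation:
    """A single signed reversal rho(i, j) or transposition rho(i, j, k).

    A reversal reverses the block at positions i..j and flips every sign
    in it; its length is j - i + 1.  A transposition exchanges the
    adjacent blocks at positions i..j-1 and j..k-1 without touching
    signs; its profile is (x, y) = (j - i, k - j).
    """

    kind: str  # "reversal" | "transposition"
    i: int
    j: int
    k: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind == "reversal":
            if self.k is not None:
                raise ValueError("a reversal takes two indices")
            if not 1 <= self.i <= self.j:
                raise ValueError(f"invalid reversal indices ({self.i}, {self.j})")
        elif self.kind == "transposition":
            if self.k is None:
                raise ValueError("a transposition takes three indices")
            if not 1 <= self.i < self.j < self.k:
                raise ValueError(
                    f"invalid transposition indices ({self.i}, {self.j}, {self.k})"
                )
        else:
            raise ValueError(f"unknown operation kind {self.kind!r}")

    @classmethod
    def reversal(cls, i: int, j: int) -> "Operation":
        return cls("reversal", i, j)

    @classmethod
    def transposition(cls, i: int, j: int, k: int) -> "Operation":
        return cls("transposition", i, j, k)

    @property
    def length(self) -> int:
        """Number of positions the operation touches."""
        if self.kind == "reversal":
            return self.j - self.i + 1
        assert self.k is not None
        return self.k - self.i

    @property
    def profile(self) -> Optional[tuple[int, int]]:
        """Block-length profile (x, y) of a transposition, else None."""
        if self.kind != "transposition":
            return None
        assert self.k is not None
        return (self.j - self.i, self.k - self.j)

    def __str__(self) -> str:
        if self.kind == "reversal":
            return f"rho({self.i},{self.j})"
        return f"rho({self.i},{self.j},{self.k})"


@dataclass(frozen=True)
class OperationFamily:
    """One of the four bounded operation models.

    SSSR: signed reversals of length <= 2 (super short reversals).
    SSR:  signed reversals of length <= 3 (short reversals).
    SSSO: SSSR plus (1,1)-transpositions (super short operations).
    SSO:  SSR plus transpositions with x + y <= 3 (short operations).
    """

    name: str
    max_reversal_length: int
    max_transposition_size: int  # max x + y; 0 = no transpositions

    def contains(self, op: Operation, n: int) -> bool:
        """Whether ``op`` is a member of the family for permutations of size n."""
        if op.kind == "reversal":
            return op.j <= n and op.length <= self.max_reversal_length
        assert op.k is not None
        x, y = op.profile  # type: ignore[misc]
        return op.k <= n + 1 and x + y <= self.max_transposition_size

    def __str__(self) -> str:
        return self.name


SSSR = OperationFamily("SSSR", max_reversal_length=2, max_transposition_size=0)
SSR = OperationFamily("SSR", max_reversal_length=3, max_transposition_size=0)
SSSO = OperationFamily("SSSO", max_reversal_length=2, max_transposition_size=2)
SSO = OperationFamily("SSO", max_reversal_length=3, max_transposition_size=3)

FAMILIES: dict[str, OperationFamily] = {
    "sssr": SSSR,
    "ssr": SSR,
    "ssso": SSSO,
    "sso": SSO,
}


def identity(n: int) -> SignedPermutation:
    """The identity permutation (+1 +2 ... +n)."""
    if n < 1:
        raise ValueError(f"permutation size must be >= 1, got {n}")
    return SignedPermutation(tuple(range(1, n + 1)))


_TOKEN_SPLIT = re.compile(r"[,\s]+")


def parse_permutation(text: str) -> SignedPermutation:
    """Parse whitespace- or comma-separated signed integers.

    The '+' sign is optional on positive elements; e.g.
    ``"+3 -4 +6 -1 +5 -2"`` or ``"3,-4,6,-1,5,-2"``.
    """
    tokens = [t for t in _TOKEN_SPLIT.split(text.strip()) if t]
    if not tokens:
        raise PermutationFormatError("empty permutation string")
    elems = []
    for tok in tokens:
        try:
            elems.append(int(tok))
        except ValueError:
            raise PermutationFormatError(f"non-integer token {tok!r}") from None
    return SignedPermutation(tuple(elems))


_RHO = re.compile(r"rho\(\s*(\d+)\s*,\s*(\d+)\s*(?:,\s*(\d+)\s*)?\)")


def parse_operations(text: str) -> list[Operation]:
    """Parse a semicolon-separated operation script in rho-notation.

    Example: ``"rho(2,4);rho(1,3);rho(1,1)"``.
    """
    ops: list[Operation] = []
    for term in text.split(";"):
        term = term.strip()
        if not term:
            continue
        m = _RHO.fullmatch(term)
        if m is None:
            raise ValueError(f"malformed operation term {term!r}")
        i, j, k = int(m.group(1)), int(m.group(2)), m.group(3)
        if k is None:
            ops.append(Operation.reversal(i, j))
        else:
            ops.append(Operation.transposition(i, j, int(k)))
    return ops


def apply_operation(p: SignedPermutation, op: Operation) -> SignedPermutation:
    """Apply a reversal or transposition, returning a new permutation."""
    e = p.elements
    n = p.n
    if op.kind == "reversal":
        if op.j > n:
            raise ValueError(f"reversal {op} out of range for n={n}")
        i, j = op.i - 1, op.j  # python slice bounds
        block = tuple(-x for x in reversed(e[i:j]))
        return SignedPermutation(e[:i] + block + e[j:])
    assert op.k is not None
    if op.k > n + 1:
        raise ValueError(f"transposition {op} out of range for n={n}")
    i, j, k = op.i - 1, op.j - 1, op.k - 1
    return SignedPermutation(e[:i] + e[j:k] + e[i:j] + e[k:])


def inversion_count(p: SignedPermutation) -> int:
    """Number of inversions Inv(p): pairs i < j with |p_i| > |p_j|.

    Counted by merge sort in O(n log n); signs are irrelevant.
    """

    def count(seq: list[int]) -> tuple[list[int], int]:
        if len(seq) <= 1:
            return seq, 0
        mid = len(seq) // 2
        left, cl = count(seq[:mid])
        right, cr = count(seq[mid:])
        merged: list[int] = []
        inv = cl + cr
        a = b = 0
        while a < len(left) and b < len(right):
            if left[a] <= right[b]:
                merged.append(left[a])
                a += 1
            else:
                inv += len(left) - a
                merged.append(right[b])
                b += 1
        merged.extend(left[a:])
        merged.extend(right[b:])
        return merged, inv

    _, c = count([abs(e) for e in p.elements])
    return c


def inversions(p: SignedPermutation) -> tuple[int, list[tuple[int, int]]]:
    """Inversion count and the inverted position pairs in lexicographic order."""
    pairs = [
        (i, j)
        for i in range(1, p.n + 1)
        for j in range(i + 1, p.n + 1)
        if abs(p[i]) > abs(p[j])
    ]
    return len(pairs), pairs


def leftmost_adjacent_inversion(p: SignedPermutation) -> Optional[int]:
    """Smallest position i with |p_i| > |p_{i+1}|, or None if sorted by magnitude.

    Whenever Inv(p) > 0 an adjacent inversion exists, so None is returned
    exactly when the permutation has no inversions at all.
    """
    for i in range(1, p.n):
        if abs(p[i]) > abs(p[i + 1]):
            return i
    return None


def enumerate_operations(n: int, family: OperationFamily) -> list[Operation]:
    """All family members for size n, in canonical order.

    Reversals come first, sorted by ascending (i, j); then transpositions
    sorted by ascending (i, j, k).  This single canonical order is the
    tie-break used by the BFS oracle and the small-component lookup
    tables; it must never vary.
    """
    if n < 1:
        raise ValueError(f"permutation size must be >= 1, got {n}")
    ops: list[Operation] = []
    for i in range(1, n + 1):
        for j in range(i, min(n, i + family.max_reversal_length - 1) + 1):
            ops.append(Operation.reversal(i, j))
    if family.max_transposition_size >= 2:
        for i in range(1, n + 1):
            for j in range(i + 1, n + 2):
                for k in range(j + 1, n + 2):
                    if (j - i) + (k - j) <= family.max_transposition_size:
                        ops.append(Operation.transposition(i, j, k))
    return ops


def inverse_operation(op: Operation) -> Operation:
    """The operation undoing ``op``.

    Reversals are involutions.  The inverse of the transposition
    rho(i, j, k) is rho(i, i + k - j, k): the two exchanged blocks swap
    roles, so the block lengths (x, y) become (y, x).  Each family is
    closed under inversion.
    """
    if op.kind == "reversal":
        return op
    assert op.k is not None
    return Operation.transposition(op.i, op.i + op.k - op.j, op.k)


def random_permutation(
    n: int, seed: int | random.Random | None = None
) -> SignedPermutation:
    """Uniform sample over all n! * 2^n signed permutations.

    A random ordering of 1..n with an independent fair sign per element.
    Passing an int seed makes the draw reproducible; passing a
    ``random.Random`` lets callers stream many draws from one generator.
    """
    if n < 1:
        raise ValueError(f"permutation size must be >= 1, got {n}")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    values = list(range(1, n + 1))
    rng.shuffle(values)
    elems = tuple(v if rng.random() < 0.5 else -v for v in values)
    return SignedPermutation(elems)


@dataclass(frozen=True)
class SortingScenario:
    """A validated sequence of family operations sorting ``start`` to identity."""

    start: SignedPermutation
    ops: tuple[Operation, ...]
    family: OperationFamily

    def __post_init__(self) -> None:
        object.__setattr__(self, "ops", tuple(self.ops))

    def __len__(self) -> int:
        return len(self.ops)

    def intermediates(self) -> list[SignedPermutation]:
        """All permutations visited, starting at ``start``."""
        states = [self.start]
        for op in self.ops:
            states.append(apply_operation(states[-1], op))
        return states

    def validate(self) -> None:
        """Raise ValueError unless every op is in-family and the result is identity."""
        p = self.start
        for step, op in enumerate(self.ops, start=1):
            if not self.family.contains(op, p.n):
                raise ValueError(
                    f"step {step}: {op} is not a {self.family.name} operation"
                )
            p = apply_operation(p, op)
        if not p.is_identity():
            raise ValueError(f"scenario ends at {p}, not the identity")

    def is_valid(self) -> bool:
        try:
            self.validate()
        except ValueError:
            return False
        return True

    def __str__(self) -> str:
        return ";".join(str(op) for op in self.ops)
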