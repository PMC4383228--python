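"""Exhaustive BFS distance tables: the exact ground truth for audits.

For any of the four operation families, a breadth-first search from the
identity over the Cayley-like state space of all n! * 2^n signed
permutations yields the exact sorting distance of every permutation.
Each family is closed under operation inverses, so the distance *from*
the identity equals the distance *to* it.

State counts grow as n! * 2^n (645,120 at n = 7), so table construction
is refused above a configurable cap rather than allowed to thrash.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterator

from .core import (
    OperationFamily,
    SignedPermutation,
    apply_operation,
    enumerate_operations,
    identity,
)

__all__ = ["DistanceTable", "build_distance_table", "exact_distance", "DEFAULT_N_CAP"]

DEFAULT_N_CAP = 7


@dataclass(frozen=True)
class DistanceTable:
    """Exact distances to the identity for every permutation of size n."""

    n: int
    family: OperationFamily
    distances: dict[tuple[int, ...], int] = field(repr=False)

    def __getitem__(self, p: SignedPermutation) -> int:
        return self.distances[p.elements]

    def __len__(self) -> int:
        return len(self.distances)

    def items(self) -> Iterator[tuple[SignedPermutation, int]]:
        for elems, d in self.distances.items():
            yield SignedPermutation(elems), d

    @property
    def max_distance(self) -> int:
        return max(self.distances.values())


def build_distance_table(
    n: int, family: OperationFamily, *, n_cap: int = DEFAULT_N_CAP
) -> DistanceTable:
    """BFS over all signed permutations of size n under a family.

    Operations are expanded in the canonical enumeration order; the
    resulting distances are order-independent.  Raises for n above
    ``n_cap`` (default 7); pass a larger cap explicitly to go beyond.
    """
    if n < 1:
        raise ValueError(f"permutation size must be >= 1, got {n}")
    if n > n_cap:
        raise ValueError(
            f"n={n} exceeds the table cap {n_cap} "
            f"({n}!*2^{n} states); pass n_cap={n} explicitly to allow it"
        )
    ops = enumerate_operations(n, family)
    start = identity(n).elements
    distances: dict[tuple[int, ...], int] = {start: 0}
    frontier = deque([start])
    while frontier:
        state = frontier.popleft()
        d = distances[state]
        p = SignedPermutation(state)
        for op in ops:
            nxt = apply_operation(p, op).elements
            if nxt not in distances:
                distances[nxt] = d + 1
                frontier.append(nxt)
    return DistanceTable(n, family, distances)


_CACHE: dict[tuple[int, str], DistanceTable] = {}


def exact_distance(
    p: SignedPermutation, family: OperationFamily, *, n_cap: int = DEFAULT_N_CAP
) -> int:
    """Exact family distance of p via a (cached) BFS table."""
    key = (p.n, family.name)
    if key not in _CACHE:
        _CACHE[key] = build_distance_table(p.n, family, n_cap=n_cap)
    return _CACHE[key][p]
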