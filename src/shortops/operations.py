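"""Sorting by length-bounded reversals *and* transpositions.

Two models:

* super short operations (2-reversals, (1,1)-transpositions and
  1-reversals): the distance is exactly Inv(p) + c_odd(p).  The optimal
  sorter removes the leftmost adjacent inversion with a
  (1,1)-transposition unless that inversion is a cut edge whose two
  sides are both odd, in which case the 2-reversal is used so that the
  number of odd components never grows;

* short operations (reversals of length <= 3 plus transpositions with
  block profile x + y <= 3): a 3-approximation dispatches on the size of
  the component containing the leftmost adjacent inversion, replaying
  precomputed shortest sorts for 3- and 4-vertex components.
"""

from __future__ import annotations

from collections import deque
from functools import lru_cache
from itertools import permutations, product
from math import ceil

from .core import (
    SSO,
    SSSO,
    Operation,
    SignedPermutation,
    SortingScenario,
    apply_operation,
    enumerate_operations,
    identity,
    inverse_operation,
    inversion_count,
    leftmost_adjacent_inversion,
)
from .graph import c_odd, components, cut_edge_split, extract_component

__all__ = [
    "ssso_distance",
    "ssso_sort",
    "small_component_table",
    "sso_sort",
    "sso_lower_bound",
]


def ssso_distance(p: SignedPermutation) -> int:
    """Exact sorting distance under super short operations: Inv(p) + c_odd(p)."""
    return inversion_count(p) + c_odd(p)[0]


def ssso_sort(p: SignedPermutation) -> SortingScenario:
    """Optimal super-short-operation scenario, of length ssso_distance(p).

    While an inversion remains, act on the leftmost adjacent one at
    position i.  If the edge (p_i, p_{i+1}) is a cut edge splitting its
    component into two odd sides, the 2-reversal rho(i, i+1) turns both
    sides even; in every other case the (1,1)-transposition
    rho(i, i+1, i+2) removes the inversion without touching parities.
    Residual negative elements are then fixed by ascending 1-reversals.
    """
    ops: list[Operation] = []
    cur = p
    while (i := leftmost_adjacent_inversion(cur)) is not None:
        split = cut_edge_split(cur, i)
        if split.is_cut and split.side_a_odd and split.side_b_odd:
            op = Operation.reversal(i, i + 1)
        else:
            op = Operation.transposition(i, i + 1, i + 2)
        ops.append(op)
        cur = apply_operation(cur, op)
    for pos in range(1, cur.n + 1):
        if cur[pos] < 0:
            op = Operation.reversal(pos, pos)
            ops.append(op)
            cur = apply_operation(cur, op)
    return SortingScenario(p, tuple(ops), SSSO)


@lru_cache(maxsize=None)
def small_component_table(
    m: int,
) -> dict[SignedPermutation, tuple[Operation, ...]]:
    """Shortest short-operation sorts for every one-component permutation of size m.

    Only m = 3 and m = 4 are supported: these are the component sizes
    the short-operation sorter cannot settle by local case analysis.
    Sequences come from one breadth-first search from the identity over
    all of S+-_m, expanding operations in the canonical enumeration
    order, so the table content is deterministic.  Every stored sequence
    has length <= Inv(sigma): a mechanical verification that every
    single-component permutation of these sizes sorts within its
    inversion count.
    """
    if m not in (3, 4):
        raise ValueError(f"small-component tables exist for m in {{3, 4}}, got {m}")
    ops = enumerate_operations(m, SSO)
    ident = identity(m)
    parent: dict[SignedPermutation, tuple[SignedPermutation, Operation] | None] = {
        ident: None
    }
    frontier = deque([ident])
    while frontier:
        state = frontier.popleft()
        for op in ops:
            nxt = apply_operation(state, op)
            if nxt not in parent:
                parent[nxt] = (state, op)
                frontier.append(nxt)

    table: dict[SignedPermutation, tuple[Operation, ...]] = {}
    for values in permutations(range(1, m + 1)):
        for signs in product((1, -1), repeat=m):
            sigma = SignedPermutation(tuple(v * s for v, s in zip(values, signs)))
            if len(components(sigma)) != 1:
                continue
            seq: list[Operation] = []
            s = sigma
            while (link := parent[s]) is not None:
                prev, op = link
                seq.append(inverse_operation(op))
                s = prev
            table[sigma] = tuple(seq)
    return table


def _translate(op: Operation, offset: int) -> Operation:
    if op.kind == "reversal":
        return Operation.reversal(op.i + offset, op.j + offset)
    assert op.k is not None
    return Operation.transposition(op.i + offset, op.j + offset, op.k + offset)


def sso_sort(p: SignedPermutation) -> SortingScenario:
    """3-approximation scenario under short operations.

    While an inversion remains, let i be the leftmost adjacent inversion
    and C the component containing it, with m vertices:

    * m >= 5: if (p_i, p_{i+1}) is not a cut edge, or both sides of
      C - e have at least 3 vertices, apply rho(i, i+1, i+2); otherwise
      the unique side with at most 2 vertices decides — even side:
      rho(i, i+1, i+2); odd side: rho(i, i+1).
    * m = 3 or 4: relabel C to a standalone permutation, replay its
      precomputed shortest short-operation sort shifted back into place.
    * m = 2: both elements negative: rho(i, i+1); otherwise
      rho(i, i+1, i+2).

    Residual negatives are fixed by ascending 1-reversals.  The scenario
    length is at most Inv(p) + c2_odd(p) + c1_odd(p) and at most three
    times the exact short-operation distance.
    """
    ops: list[Operation] = []
    cur = p
    while (i := leftmost_adjacent_inversion(cur)) is not None:
        comp = components(cur).component_at(i)
        m = comp.vertex_count
        if m >= 5:
            split = cut_edge_split(cur, i)
            if not split.is_cut or (
                split.side_a_vertices >= 3 and split.side_b_vertices >= 3
            ):
                step_ops = [Operation.transposition(i, i + 1, i + 2)]
            else:
                sides = [
                    (split.side_a_vertices, split.side_a_odd),
                    (split.side_b_vertices, split.side_b_odd),
                ]
                small = [s for s in sides if s[0] <= 2]
                assert len(small) == 1, "sides sum to m >= 5"
                if small[0][1]:
                    step_ops = [Operation.reversal(i, i + 1)]
                else:
                    step_ops = [Operation.transposition(i, i + 1, i + 2)]
        elif m in (3, 4):
            sigma = extract_component(cur, (comp.start, comp.end))
            seq = small_component_table(m)[sigma]
            step_ops = [_translate(op, comp.start - 1) for op in seq]
        else:  # m == 2; the adjacent inversion lies inside this component
            if cur[i] < 0 and cur[i + 1] < 0:
                step_ops = [Operation.reversal(i, i + 1)]
            else:
                step_ops = [Operation.transposition(i, i + 1, i + 2)]
        for op in step_ops:
            ops.append(op)
            cur = apply_operation(cur, op)
    for pos in range(1, cur.n + 1):
        if cur[pos] < 0:
            op = Operation.reversal(pos, pos)
            ops.append(op)
            cur = apply_operation(cur, op)
    return SortingScenario(p, tuple(ops), SSO)


def sso_lower_bound(p: SignedPermutation) -> int:
    """Lower bound on the short-operation distance.

    A short operation changes Inv + c_odd by at most four, and
    Inv + c2_odd + c1_odd by at most three; the maximum of the two
    ceilings is returned.
    """
    total, one, two = c_odd(p)
    inv = inversion_count(p)
    return max(ceil((inv + total) / 4), ceil((inv + two + one) / 3))
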