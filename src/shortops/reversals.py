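"""Sorting by length-bounded signed reversals.

Two models are covered:

* super short reversals (length <= 2): the distance has a closed form,
  Inv(p) + |V^even-| + |V^odd+|, realized constructively by removing
  adjacent inversions with 2-reversals and cleaning residual negative
  signs with 1-reversals;

* short reversals (length <= 3): the distance is not known to be
  polynomial; a two-phase 5-approximation repeatedly swaps
  vector-opposite pairs (each swap of an m-apart pair costs
  2*ceil(m/2) - 1 reversals and lowers Vec by 2m), then flips residual
  negatives.
"""

from __future__ import annotations

from math import ceil

from .core import (
    SSR,
    SSSR,
    Operation,
    SignedPermutation,
    SortingScenario,
    apply_operation,
    inversion_count,
    leftmost_adjacent_inversion,
)
from .vectors import (
    find_vector_opposite_pair,
    swap_sequence,
    vec_total,
    vector_subset_sizes,
)

__all__ = ["sssr_distance", "sssr_sort", "ssr_sort", "ssr_lower_bound"]


def sssr_distance(p: SignedPermutation) -> int:
    """Exact sorting distance under signed reversals of length <= 2.

    Equals Inv(p) + |V^even-| + |V^odd+|: every inversion costs one
    2-reversal, and the elements that remain negative after all
    2-reversals — negatives with even vector length plus positives with
    odd vector length — each cost one 1-reversal.
    """
    sizes = vector_subset_sizes(p)
    return inversion_count(p) + sizes.even_neg + sizes.odd_pos


def sssr_sort(p: SignedPermutation) -> SortingScenario:
    """Optimal super-short-reversal scenario, of length sssr_distance(p).

    2-reversals are applied at the leftmost adjacent inversion until no
    inversion remains (any choice is optimal; leftmost keeps scenarios
    reproducible), then 1-reversals at the remaining negative positions
    in ascending order.
    """
    ops: list[Operation] = []
    cur = p
    while (i := leftmost_adjacent_inversion(cur)) is not None:
        op = Operation.reversal(i, i + 1)
        ops.append(op)
        cur = apply_operation(cur, op)
    for pos in range(1, cur.n + 1):
        if cur[pos] < 0:
            op = Operation.reversal(pos, pos)
            ops.append(op)
            cur = apply_operation(cur, op)
    return SortingScenario(p, tuple(ops), SSSR)


def ssr_sort(p: SignedPermutation) -> SortingScenario:
    """5-approximation scenario under signed reversals of length <= 3.

    Phase one: while a vector-opposite pair exists, swap the pair found
    by the pinned pair-finding rule with its short-reversal swap
    sequence; each swap strictly reduces Vec, so the phase terminates
    with all magnitudes in place.  Phase two: 1-reversals at the
    remaining negative positions in ascending order.  No opportunistic
    1-reversals are interleaved into phase one.
    """
    ops: list[Operation] = []
    cur = p
    while (pair := find_vector_opposite_pair(cur)) is not None:
        seq = swap_sequence(cur, *pair)
        for op in seq:
            cur = apply_operation(cur, op)
        ops.extend(seq)
    for pos in range(1, cur.n + 1):
        if cur[pos] < 0:
            op = Operation.reversal(pos, pos)
            ops.append(op)
            cur = apply_operation(cur, op)
    return SortingScenario(p, tuple(ops), SSR)


def ssr_lower_bound(p: SignedPermutation) -> int:
    """Lower bound on the short-reversal distance.

    Combines two potential arguments: a short reversal removes at most
    three inversions and fixes at most three signs, giving
    (Inv + |V^even-| + |V^odd+|) / 6; and it changes
    Vec + |V^odd| + |V^0-| by at most five, giving
    (Vec + |V^odd| + |V^0-|) / 5.  The two bounds are incomparable, so
    the maximum of their ceilings is taken.
    """
    sizes = vector_subset_sizes(p)
    inv = inversion_count(p)
    b1 = ceil((inv + sizes.even_neg + sizes.odd_pos) / 6)
    b2 = ceil((vec_total(p) + sizes.odd + sizes.zero_neg) / 5)
    return max(b1, b2)
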