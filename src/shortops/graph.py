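"""Permutation graph and its component decomposition.

The permutation graph G_p of a signed permutation p has the elements as
vertices and one edge per inversion pair.  Its connected components
occupy consecutive position intervals whose absolute values are exactly
that interval of integers (a "complete substring"), so the whole
decomposition falls out of a single linear scan: repeatedly grow the
current interval until the running maximum of |p_i| equals the interval
end.

A component is odd when it contains an odd number of negative elements.
Inv(p) + c_odd(p) is the exact sorting distance under super short
operations, and the odd components with one or two vertices drive the
3-approximation for short operations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import SignedPermutation

__all__ = [
    "Component",
    "ComponentDecomposition",
    "CutEdgeSplit",
    "components",
    "c_odd",
    "cut_edge_split",
    "extract_component",
]


@dataclass(frozen=True)
class Component:
    """One connected component: the position interval [start, end]."""

    start: int
    end: int
    negative_count: int

    @property
    def vertex_count(self) -> int:
        return self.end - self.start + 1

    @property
    def is_odd(self) -> bool:
        return self.negative_count % 2 == 1

    @property
    def parity(self) -> str:
        return "odd" if self.is_odd else "even"


@dataclass(frozen=True)
class ComponentDecomposition:
    """Ordered components partitioning positions 1..n."""

    parts: tuple[Component, ...]

    def __iter__(self):
        return iter(self.parts)

    def __len__(self) -> int:
        return len(self.parts)

    def component_at(self, pos: int) -> Component:
        """The component whose interval contains the given position."""
        for c in self.parts:
            if c.start <= pos <= c.end:
                return c
        raise ValueError(f"position {pos} outside 1..n")


def components(p: SignedPermutation) -> ComponentDecomposition:
    """Connected components of the permutation graph, in O(n).

    Starting at the first unassigned position i, the minimum complete
    substring beginning at i closes at the first j where
    max(|p_i|, ..., |p_j|) == j; that interval is one component.
    """
    parts: list[Component] = []
    start = 1
    running_max = 0
    negatives = 0
    for pos in range(1, p.n + 1):
        e = p[pos]
        running_max = max(running_max, abs(e))
        if e < 0:
            negatives += 1
        if running_max == pos:
            parts.append(Component(start, pos, negatives))
            start = pos + 1
            negatives = 0
    return ComponentDecomposition(tuple(parts))


def c_odd(p: SignedPermutation) -> tuple[int, int, int]:
    """(c_odd, c1_odd, c2_odd): odd components overall and with 1 or 2 vertices."""
    total = one = two = 0
    for comp in components(p):
        if comp.is_odd:
            total += 1
            if comp.vertex_count == 1:
                one += 1
            elif comp.vertex_count == 2:
                two += 1
    return total, one, two


@dataclass(frozen=True)
class CutEdgeSplit:
    """Effect of deleting the edge (p_i, p_{i+1}) from its component.

    side_a is the side containing position i; sides are reported only
    when the edge exists and is a cut edge.
    """

    exists_edge: bool
    is_cut: bool
    side_a_vertices: int = 0
    side_a_negatives: int = 0
    side_b_vertices: int = 0
    side_b_negatives: int = 0

    @property
    def side_a_odd(self) -> bool:
        return self.side_a_negatives % 2 == 1

    @property
    def side_b_odd(self) -> bool:
        return self.side_b_negatives % 2 == 1


def _inversion_edges(p: SignedPermutation, lo: int, hi: int) -> list[tuple[int, int]]:
    return [
        (i, j)
        for i in range(lo, hi + 1)
        for j in range(i + 1, hi + 1)
        if abs(p[i]) > abs(p[j])
    ]


def cut_edge_split(p: SignedPermutation, i: int) -> CutEdgeSplit:
    """Analyze the adjacent edge e = (p_i, p_{i+1}) of the permutation graph.

    The edge exists iff (p_i, p_{i+1}) is an inversion.  It is a cut edge
    iff deleting it disconnects its component; the two resulting sides
    are then reported with vertex counts and negative counts.  Works on
    the component restricted to its interval, so the cost is quadratic in
    the component size only.
    """
    if not 1 <= i < p.n:
        raise ValueError(f"need 1 <= i < n, got i={i}, n={p.n}")
    if abs(p[i]) <= abs(p[i + 1]):
        return CutEdgeSplit(exists_edge=False, is_cut=False)
    comp = components(p).component_at(i)
    edges = [
        e for e in _inversion_edges(p, comp.start, comp.end) if e != (i, i + 1)
    ]
    # union-find over the component's positions without the deleted edge
    parent = {pos: pos for pos in range(comp.start, comp.end + 1)}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)

    root_a = find(i)
    if find(i + 1) == root_a:
        return CutEdgeSplit(exists_edge=True, is_cut=False)
    side_a = [pos for pos in range(comp.start, comp.end + 1) if find(pos) == root_a]
    side_b = [pos for pos in range(comp.start, comp.end + 1) if find(pos) != root_a]
    return CutEdgeSplit(
        exists_edge=True,
        is_cut=True,
        side_a_vertices=len(side_a),
        side_a_negatives=sum(1 for pos in side_a if p[pos] < 0),
        side_b_vertices=len(side_b),
        side_b_negatives=sum(1 for pos in side_b if p[pos] < 0),
    )


def extract_component(
    p: SignedPermutation, interval: tuple[int, int]
) -> SignedPermutation:
    """Relabel a component's interval into a standalone signed permutation.

    For the component spanning [start, end], returns sigma of size
    end - start + 1 with the offset start - 1 subtracted from each
    magnitude and signs preserved; sigma's permutation graph is
    isomorphic to the component.
    """
    start, end = interval
    if not any((c.start, c.end) == (start, end) for c in components(p)):
        raise ValueError(f"[{start}, {end}] is not a component of {p}")
    offset = start - 1
    elems = tuple(
        e - offset if e > 0 else e + offset for e in p.elements[start - 1 : end]
    )
    return SignedPermutation(elems)
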