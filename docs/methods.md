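# Methods

## Model

A genome with a single linear chromosome, a shared gene set, and no
duplicate genes is a signed permutation π ∈ S±ₙ: an ordering of 1..n where
each element carries an orientation. Two operation kinds act on it. A
signed reversal ρ(i, j), 1 ≤ i ≤ j ≤ n, reverses the block at positions
i..j and negates every element in it; its length is j − i + 1. A
transposition ρ(i, j, k), 1 ≤ i < j < k ≤ n + 1, exchanges the adjacent
blocks at positions i..j−1 and j..k−1 without changing signs; its block
profile is (x, y) = (j − i, k − j), and k may equal n + 1 so the second
block can end at the last position. All positions are 1-based in the public
API.

Four operation families bound the length of what a single event may touch:

* **SSSR** — reversals of length ≤ 2;
* **SSR** — reversals of length ≤ 3;
* **SSSO** — SSSR plus (1,1)-transpositions (adjacent swaps keeping signs);
* **SSO** — SSR plus transpositions with x + y ≤ 3.

1-reversals (bare sign flips) belong to every family. The families are
closed under operation inverses: reversals are involutions and the inverse
of ρ(i, j, k) is ρ(i, i + k − j, k), which has the transposed profile
(y, x).

The distance d_F(π) is the minimum number of family-F operations
transforming π into the identity. Because every family contains the 1- and
2-reversals, which generate the full signed symmetric group, every
permutation is sortable in every model.

## Exact models

**Super short reversals.** A 2-reversal removes or creates exactly one
inversion; a 1-reversal changes none. So Inv(π) 2-reversals are necessary
and sufficient to fix all magnitudes, and the only question is how many
1-reversals the signs cost. Assign each element the vector length
||π_i| − i|. A 2-reversal flips both affected signs *and* both vector-length
parities, so the count of elements that are negative-with-even-length or
positive-with-odd-length (|V^even−| + |V^odd+|) is invariant under
2-reversals — and these are precisely the elements still negative once all
inversions are gone. Hence

    d_sssr(π) = Inv(π) + |V^even−| + |V^odd+|.

The optimal sorter applies the 2-reversal at the *leftmost* adjacent
inversion until none remains, then 1-reversals in ascending position order.
Any adjacent-inversion choice is optimal; leftmost is fixed purely so that
emitted scenarios are reproducible, and likewise for the cleanup order.

**Super short operations.** With (1,1)-transpositions available, signs can
ride along with a swap. On the permutation graph G_π (vertices = elements,
edges = inversion pairs) define a component *odd* if it contains an odd
number of negative elements. A super short operation applied to an
inversion can never reduce the number of odd components c_odd, and a
(1,1)-transposition that would increase it (a cut edge whose two sides are
both odd) can always be replaced by the 2-reversal on the same inversion,
which makes both sides even. This gives

    d_ssso(π) = Inv(π) + c_odd(π),

realized by: at the leftmost adjacent inversion i, apply ρ(i, i+1) if the
edge (π_i, π_{i+1}) is a cut edge with two odd sides, else ρ(i, i+1, i+2);
finish with ascending 1-reversals.

Components are computed by a linear scan: the component starting at
position i closes at the first j where max(|π_i|..|π_j|) = j (the minimum
"complete substring"), since component vertex sets always occupy
consecutive position intervals whose magnitudes form exactly that integer
interval. Cut-edge queries recompute connectivity of the one affected
component with union-find after deleting the edge — O(component²), which is
irrelevant at the scale this package targets (n ≤ 7 for exhaustive work).

## Approximation models

**Short reversals (5-approximation).** Give each element a direction: right
if |π_i| > i, left if |π_i| < i; zero-length vectors keep an explicit
polarity (zero+ for π_i = i, zero− for π_i = −i). Elements at positions
i < j are *m-vector-opposite* (m = j − i) if the vector at i points right,
the one at j points left, and both lengths are ≥ m — i.e. they can swap
places without either overshooting its target. Swapping such a pair costs
2⌈m/2⌉ − 1 short reversals (a ladder of 3-reversals, with one 2-reversal in
the middle when m is odd) and reduces the total vector length Vec(π) by
exactly 2m. The sorter repeats: find a pair with the pinned rule below,
apply its swap ladder; when Vec = 0, flip remaining negatives with
1-reversals. No opportunistic 1-reversals are interleaved. The count A2(π)
satisfies

    max(⌈(Inv + |V^even−| + |V^odd+|)/6⌉, ⌈(Vec + |V^odd| + |V^0−|)/5⌉)
        ≤ d_ssr(π) ≤ A2(π) ≤ 5 · d_ssr(π),

and A2(π) ≤ 3 · d_ssr(π) whenever Vec(π) = 0 or Vec(π) ≥ 4n. Since the
expected Vec of a uniform random signed permutation is (n² − 1)/3 (each
position-summed vector-length probability is Σ_i Pr(|v(π_i)| = j) =
2(n − j)/n), the expected ratio is ≤ 3 once (n² − 1)/3 ≥ 4n, i.e. n ≥ 13.
The two lower-bound arguments are never combined in a single potential;
taking the max of the two ceilings is a (valid) strengthening and is
flagged as such here.

*Pinned pair-finding rule.* Let i be the position of the rightmost right
vector and k = |π_i|; let j be the leftmost left vector in (i, k] (one must
exist). If j = i + 1 but (i, i + 2) is 2-vector-opposite, return (i, i + 2);
else return (i, j). The override matters for the approximation analysis: an
adjacent pair whose two vector lengths are both even makes no potential
progress on its own, and the guarantee that no 2-vector-opposite pair was
available at i rules the bad case out. Only the pointing-toward-each-other
reading of "differ in direction" is used — vectors pointing away from each
other would *increase* Vec by 2m when swapped. Ties among left vectors are
resolved literally leftmost. Every downstream audit number depends on this
exact tie-break.

**Short operations (3-approximation).** Refine c_odd by component size:
c¹_odd and c²_odd count odd components with exactly 1 and 2 vertices. The
sorter acts at the leftmost adjacent inversion i inside its component C
(m vertices):

* m ≥ 5 — if (π_i, π_{i+1}) is not a cut edge, or both sides of C − e have
  ≥ 3 vertices, apply ρ(i, i+1, i+2); otherwise exactly one side has ≤ 2
  vertices (the sides sum to m ≥ 5): apply ρ(i, i+1, i+2) if that side is
  even, ρ(i, i+1) if odd. The parity test is applied to whichever side is
  small, not specifically to the side containing π_i.
* m = 3 or 4 — relabel C to a standalone σ ∈ S±_m (subtract the interval
  offset from magnitudes, keep signs; the graph is isomorphic) and replay a
  precomputed shortest SSO sort of σ shifted back into place.
* m = 2 — both elements negative: ρ(i, i+1); otherwise ρ(i, i+1, i+2).

Then ascending 1-reversals. The count satisfies

    max(⌈(Inv + c_odd)/4⌉, ⌈(Inv + c²_odd + c¹_odd)/3⌉)
        ≤ d_sso(π) ≤ A5(π) ≤ min(3 · d_sso(π), Inv + c²_odd + c¹_odd),

and the ratio 3 is attained (at n = 5 already), so the bound is tight.

*Small-component tables.* For m ∈ {3, 4}, one BFS from the identity over
all of S±_m under SSO, expanding operations in the canonical order
(reversals before transpositions, lexicographic indices, FIFO frontier,
first-discovered parent kept), yields for every single-component σ a
shortest sorting sequence by walking parent pointers and inverting each
step. Every stored sequence has length ≤ Inv(σ) — the mechanical
verification behind the m ∈ {3, 4} dispatch — and shortest sequences make
the per-permutation operation counts reproducible run to run. The tables
are built lazily once per process and cached; their content is independent
of build order.

## Oracle and audit

The BFS oracle enumerates all n!·2ⁿ signed permutations from the identity
under any family; closure under inverses makes distance-from-identity equal
distance-to-identity. States are fixed-length integer tuples in a flat
dict. n = 7 (645,120 states) fits easily in memory; larger n is refused
unless the cap is raised explicitly, rather than allowed to thrash.

The audit enumerates every π ∈ S±ₙ, runs a sorter, and compares its count
with the oracle distance. The ratio is defined as 1 when the exact distance
is 0, so the identity counts as exactly solved — the convention that
reproduces 100% exact at n = 1, where the identity is half the population.
Aggregation uses exact rational arithmetic; rounding (half-up, two
decimals) happens only at presentation. Audits run exhaustively for n ≤ 5
(seconds on one CPU); n = 6–7 sit behind an explicit CLI flag (minutes);
n ≥ 8 is refused — ~10.3M states at n = 8 and ~3.7G at n = 10 put a full
audit of the largest published sizes outside the intended scale, and the
theorems' ratio bounds (≤ 5 and ≤ 3) are verified as properties instead.

## Randomness

`random_permutation` draws uniformly over all n!·2ⁿ signed permutations: a
Fisher–Yates shuffle of the values plus an independent fair sign per
element, from a caller-supplied seed or `random.Random`. The Monte-Carlo
check of the expected-Vec closed form uses 10⁴ seeded samples at n = 13
(theoretical mean 56) and a 3-standard-error acceptance band computed from
the sample standard deviation.

## Scope and limitations

* Exact distances for the short models (SSR, SSO) are open problems; this
  package provides the approximation sorters, their lower bounds, and
  BFS-exact values at small n only.
* Linear genomes only: circular permutations are a genuinely different
  problem for bounded-length operations, and weighted-by-length operation
  costs are out of scope.
* The audit's per-permutation counts at n ≥ 4 depend on the pinned
  tie-breaks (leftmost adjacent inversion, the pair-finding rule,
  BFS-canonical small-component sequences). These choices reproduce all
  hand-checkable published audit rows (both tables at n ≤ 3, the
  short-reversal row at n = 4, and both worst-case traces), but other valid
  tie-breaks could shift average/exact cells at larger n.
* Uniform random signed permutations model no real mutational process;
  the expected-ratio result says nothing about biased gene orders.
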