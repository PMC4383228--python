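# shortops

Sorting signed permutations by **length-bounded** rearrangement operations.

Comparative genomics estimates the evolutionary distance between two
unichromosomal genomes as the minimum number of rearrangement events —
reversals and transpositions — transforming one gene order into the other,
which reduces to sorting a signed permutation π ∈ S±ₙ into the identity
ι = (+1 +2 … +n). Because rearrangements spanning few genes are believed to
dominate in many bacterial and lower-eukaryote lineages, this package
restricts the operations to *short* variants and implements four models:

| model | operations allowed                                   | solver                |
|-------|------------------------------------------------------|-----------------------|
| SSSR  | signed reversals of length ≤ 2                       | exact, closed form    |
| SSR   | signed reversals of length ≤ 3                       | 5-approximation       |
| SSSO  | SSSR plus (1,1)-transpositions                       | exact, closed form    |
| SSO   | SSR plus transpositions with block profile x + y ≤ 3 | 3-approximation       |

A signed reversal ρ(i, j) reverses the block at positions i..j and flips its
signs; a transposition ρ(i, j, k) exchanges the adjacent blocks i..j−1 and
j..k−1. With Inv(π) the number of pairs i < j, |π_i| > |π_j|, the exact
distances are

- d_sssr(π) = Inv(π) + |V^even−| + |V^odd+|, where the two terms count
  negative elements with even *vector length* ||π_i| − i| and positive
  elements with odd vector length — exactly the elements still negative
  after all inversions are removed by 2-reversals;
- d_ssso(π) = Inv(π) + c_odd(π), where c_odd counts connected components of
  the permutation graph (one edge per inversion) containing an odd number of
  negative elements.

The two approximation sorters carry matching lower bounds, and an exhaustive
breadth-first-search oracle computes exact distances for any model at small
n, enabling a full audit of the approximation quality over every signed
permutation of a given size.

## Worked example

The permutation (+3 +4 −1 −2) is the worst case of the short-reversal
5-approximation:

```
$ shortops sort --model ssr --perm "+3 +4 -1 -2"
permutation: +3 +4 -1 -2
model:       ssr
operations:  rho(2,4);rho(1,3);rho(1,1);rho(2,2);rho(3,3);rho(4,4)
count:       6
```

Six short reversals: two 3-reversals place all magnitudes (each swap of a
vector-opposite pair), then four 1-reversals fix the signs. The exact
short-reversal distance is 2 (ρ(1,3) then ρ(2,4)), so the ratio is 3. The
exact models have closed forms:

```
$ shortops distance --model sssr --perm "-3 -2 -1"
sssr distance: 6
```

(3 inversions plus 3 elements that remain negative), and the audit command
reproduces the approximation-quality tables by enumerating all n!·2ⁿ
permutations against the BFS oracle:

```
$ shortops audit --algorithm sso --max-n 5
  n  avg_ratio  max_ratio     exact
  1       1.00       1.00   100.00%
  2       1.00       1.00   100.00%
  3       1.04       1.50    91.67%
  4       1.02       1.50    93.75%
  5       1.31       3.00    46.41%
```

`avg_ratio` / `max_ratio` compare the sorter's operation count with the
exact distance; `exact` is the share of permutations solved optimally. The
max ratio can never exceed 3 for the short-operation sorter (or 5 for the
short-reversal one), and the ratio 3.00 at n = 5 shows the bound is tight.

Other subcommands: `distance --oracle` (BFS-exact), `verify` (check an
operation script), `random` (seeded uniform sampling), `oracle --dump`
(full distance table as TSV).

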