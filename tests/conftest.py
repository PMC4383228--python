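from itertools import permutations, product

import pytest

from shortops import SignedPermutation, parse_permutation


def all_perms(n: int):
    """All n! * 2^n signed permutations of size n."""
    for values in permutations(range(1, n + 1)):
        for signs in product((1, -1), repeat=n):
            yield SignedPermutation(tuple(v * s for v, s in zip(values, signs)))


def brute_inversions(p: SignedPermutation) -> int:
    return sum(
        1
        for i in range(1, p.n + 1)
        for j in range(i + 1, p.n + 1)
        if abs(p[i]) > abs(p[j])
    )


@pytest.fixture
def figure_perm() -> SignedPermutation:
    """The running example permutation (+3 -4 +6 -1 +5 -2)."""
    return parse_permutation("+3 -4 +6 -1 +5 -2")


@pytest.fixture
def reversed_negative_3() -> SignedPermutation:
    """(-3 -2 -1): sortable by one 3-reversal, costly in shorter models."""
    return parse_permutation("-3 -2 -1")
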