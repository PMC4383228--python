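import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shortops import (
    FAMILIES,
    SSO,
    SSR,
    SSSO,
    SSSR,
    Operation,
    PermutationFormatError,
    SignedPermutation,
    SortingScenario,
    apply_operation,
    enumerate_operations,
    identity,
    inverse_operation,
    inversion_count,
    inversions,
    leftmost_adjacent_inversion,
    parse_operations,
    parse_permutation,
    random_permutation,
)

from conftest import all_perms, brute_inversions


class TestParsing:
    def test_paper_example(self):
        p = parse_permutation("+3 -4 +6 -1 +5 -2")
        assert p.elements == (3, -4, 6, -1, 5, -2)

    @pytest.mark.parametrize(
        "text, elems",
        [
            ("1", (1,)),
            ("3,-4,6,-1,5,-2", (3, -4, 6, -1, 5, -2)),
            ("  +2  -1 ", (2, -1)),
        ],
    )
    def test_accepted_formats(self, text, elems):
        assert parse_permutation(text).elements == elems

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("+1 +1", "duplicate"),
            ("0 1", "0"),
            ("1 3", "missing"),
            ("1 two", "two"),
            ("", "empty"),
        ],
    )
    def test_rejected_formats(self, text, fragment):
        with pytest.raises((PermutationFormatError, ValueError)) as exc:
            parse_permutation(text)
        assert fragment in str(exc.value)

    def test_format_prints_explicit_plus(self):
        assert str(parse_permutation("3 -4 1 -2")) == "+3 -4 +1 -2"

    @given(n=st.integers(1, 30), seed=st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=40)
    def test_parse_format_roundtrip(self, n, seed):
        p = random_permutation(n, seed)
        assert parse_permutation(str(p)) == p


class TestIdentity:
    def test_small(self):
        assert identity(3).elements == (1, 2, 3)
        assert identity(1).elements == (1,)
        assert identity(5).is_identity()

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            identity(0)


class TestApplyOperation:
    def test_full_reversal_sorts_descending_negatives(self):
        p = parse_permutation("-3 -2 -1")
        assert apply_operation(p, Operation.reversal(1, 3)).is_identity()

    def test_reversal_negates_and_reverses_block(self):
        p = parse_permutation("+3 +4 -1 -2")
        assert apply_operation(p, Operation.reversal(1, 3)).elements == (1, -4, -3, -2)

    def test_transposition_swaps_blocks_keeping_signs(self):
        p = parse_permutation("-3 -2 -5 -4 +1")
        got = apply_operation(p, Operation.transposition(1, 2, 3))
        assert got.elements == (-2, -3, -5, -4, 1)

    def test_transposition_upper_index_may_be_n_plus_1(self):
        p = parse_permutation("+2 +3 +1")
        got = apply_operation(p, Operation.transposition(1, 3, 4))
        assert got.is_identity()

    def test_out_of_range_rejected(self):
        p = identity(3)
        with pytest.raises(ValueError):
            apply_operation(p, Operation.reversal(2, 4))
        with pytest.raises(ValueError):
            apply_operation(p, Operation.transposition(2, 3, 5))


class TestInversions:
    def test_identity_has_none(self):
        assert inversions(identity(6)) == (0, [])

    def test_descending_triple(self):
        count, pairs = inversions(parse_permutation("-3 -2 -1"))
        assert count == 3
        assert pairs == [(1, 2), (1, 3), (2, 3)]

    def test_running_example(self, figure_perm):
        assert inversion_count(figure_perm) == 8

    @given(n=st.integers(1, 50), seed=st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=40)
    def test_fast_count_matches_brute_force(self, n, seed):
        p = random_permutation(n, seed)
        assert inversion_count(p) == brute_inversions(p)


class TestLeftmostAdjacentInversion:
    def test_none_iff_no_inversions(self):
        assert leftmost_adjacent_inversion(identity(4)) is None
        for p in all_perms(4):
            pos = leftmost_adjacent_inversion(p)
            assert (pos is None) == (inversion_count(p) == 0)

    def test_examples(self):
        assert leftmost_adjacent_inversion(parse_permutation("-2 -3 -5 -4 +1")) == 3
        assert leftmost_adjacent_inversion(parse_permutation("-3 -2 -1")) == 1


class TestEnumerateOperations:
    @pytest.mark.parametrize(
        "n, family, expected",
        [
            (3, SSSR, 5),  # three 1-reversals, two 2-reversals
            (3, SSR, 6),
            (3, SSSO, 7),
            (3, SSO, 10),  # 6 reversals, 2 (1,1)-, 1 (1,2)-, 1 (2,1)-transpositions
            (1, SSR, 1),
        ],
    )
    def test_counts(self, n, family, expected):
        assert len(enumerate_operations(n, family)) == expected

    def test_canonical_order_reversals_first_lexicographic(self):
        ops = enumerate_operations(3, SSO)
        kinds = [op.kind for op in ops]
        assert kinds == ["reversal"] * 6 + ["transposition"] * 4
        rev_keys = [(op.i, op.j) for op in ops[:6]]
        assert rev_keys == sorted(rev_keys)
        tr_keys = [(op.i, op.j, op.k) for op in ops[6:]]
        assert tr_keys == sorted(tr_keys)

    def test_members_belong_to_family(self):
        for name, family in FAMILIES.items():
            for op in enumerate_operations(4, family):
                assert family.contains(op, 4), (name, op)

    def test_family_nesting(self):
        sssr = set(enumerate_operations(4, SSSR))
        ssr = set(enumerate_operations(4, SSR))
        ssso = set(enumerate_operations(4, SSSO))
        sso = set(enumerate_operations(4, SSO))
        assert sssr < ssr < sso
        assert sssr < ssso < sso


class TestInverseOperation:
    def test_reversals_are_involutions(self):
        op = Operation.reversal(2, 4)
        assert inverse_operation(op) == op

    def test_transposition_inverse_swaps_block_profile(self):
        assert inverse_operation(Operation.transposition(1, 2, 4)) == (
            Operation.transposition(1, 3, 4)
        )
        op = Operation.transposition(1, 2, 3)
        assert inverse_operation(op) == op

    def test_inverse_restores_exhaustively(self):
        # every family op on every signed permutation of size <= 4
        for n in (2, 3, 4):
            ops = enumerate_operations(n, SSO)
            for p in all_perms(n):
                for op in ops:
                    inv = inverse_operation(op)
                    assert SSO.contains(inv, n)
                    assert apply_operation(apply_operation(p, op), inv) == p


class TestRandomPermutation:
    def test_deterministic_for_same_seed(self):
        assert random_permutation(5, 123) == random_permutation(5, 123)

    def test_size_one_support(self):
        assert random_permutation(1, 7).elements in {(1,), (-1,)}

    def test_uniform_over_all_48_at_n3(self):
        # 10^5 draws; each of the 48 outcomes within 4 standard errors
        rng = random.Random(2026)
        counts = {}
        samples = 100_000
        for _ in range(samples):
            p = random_permutation(3, rng)
            counts[p.elements] = counts.get(p.elements, 0) + 1
        assert len(counts) == 48
        expected = samples / 48
        se = (samples * (1 / 48) * (47 / 48)) ** 0.5
        for c in counts.values():
            assert abs(c - expected) <= 4 * se


class TestInversionChangeBounds:
    def test_exhaustive_bounds_by_operation_class(self):
        """A super short op shifts Inv by at most 1, a short transposition
        by at most 2, a short reversal by at most 3 — over all of S+-_4."""
        ops = enumerate_operations(4, SSO)
        for p in all_perms(4):
            inv = inversion_count(p)
            for op in ops:
                delta = inv - inversion_count(apply_operation(p, op))
                if SSSO.contains(op, 4):
                    assert abs(delta) <= 1
                elif op.kind == "transposition":
                    assert abs(delta) <= 2
                else:
                    assert abs(delta) <= 3


class TestSortingScenario:
    def test_valid_scenario(self):
        p = parse_permutation("-3 -2 -1")
        s = SortingScenario(p, (Operation.reversal(1, 3),), SSR)
        s.validate()
        assert s.is_valid()
        assert len(s) == 1
        assert s.intermediates()[-1].is_identity()

    def test_out_of_family_op_rejected(self):
        p = parse_permutation("-3 -2 -1")
        s = SortingScenario(p, (Operation.reversal(1, 3),), SSSR)
        with pytest.raises(ValueError, match="SSSR"):
            s.validate()

    def test_not_reaching_identity_rejected(self):
        s = SortingScenario(identity(3), (Operation.reversal(1, 1),), SSR)
        assert not s.is_valid()

    def test_script_roundtrip(self):
        ops = (
            Operation.reversal(2, 4),
            Operation.transposition(1, 2, 3),
            Operation.reversal(1, 1),
        )
        text = ";".join(str(op) for op in ops)
        assert tuple(parse_operations(text)) == ops
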