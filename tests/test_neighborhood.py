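import string
from collections import Counter

import pytest

from emsmotif import (
    Alphabet,
    InvalidParameterError,
    expand_compact,
    gen_all,
    gen_friends,
    oracle_motifs_one_string,
    phase_plan,
    skip_rule,
)
from emsmotif.neighborhood import OP_ORDER

from conftest import random_dna


def expansions(neighbors, alphabet=None):
    out = set()
    for nb in neighbors:
        out |= (
            expand_compact(nb.motif)
            if alphabet is None
            else expand_compact(nb.motif, alphabet)
        )
    return out


class TestPhasePlan:
    def test_longest_kmer_forces_pure_deletions(self):
        assert phase_plan(10, 8, 2).triples == ((2, 0, 0),)

    def test_equal_length_kmer(self):
        assert phase_plan(8, 8, 2).triples == ((0, 2, 0), (1, 0, 1))

    def test_short_kmer_single_insertion(self):
        assert phase_plan(7, 8, 1).triples == ((0, 0, 1),)

    def test_out_of_range_k_rejected(self):
        with pytest.raises(InvalidParameterError):
            phase_plan(6, 8, 1)

    def test_triples_satisfy_arithmetic(self):
        for l in range(2, 7):
            for d in range(0, l):
                for k in range(l - d, l + d + 1):
                    plan = phase_plan(k, l, d)
                    assert len(plan.triples) >= 1
                    for delta, beta, alpha in plan:
                        assert delta + beta + alpha == d
                        assert k - delta + alpha == l


class TestSkipRules:
    def test_leftmost_deletion_skipped_unless_rightmost_kmer(self):
        assert skip_rule(1, 3, 4, [(1, "D")]) == 1
        assert skip_rule(2, 3, 4, [(2, "D")]) is None  # j+k = 5 > m

    def test_substitution_after_deletion(self):
        assert skip_rule(1, 4, 8, [(2, "D"), (3, "R")]) == 2

    def test_leftmost_insertion_requires_non_leftmost_kmer(self):
        assert skip_rule(1, 2, 6, [(1, "I")]) is None
        assert skip_rule(2, 2, 6, [(2, "I")]) == 7

    def test_right_end_insertion(self):
        assert skip_rule(3, 2, 4, [(5, "I")]) is None  # j+k = 5 > m
        assert skip_rule(2, 2, 4, [(4, "I")]) == 9

    def test_substitution_run_then_deletion(self):
        assert skip_rule(1, 4, 8, [(1, "R"), (2, "D")]) == 3
        # rightmost k-mer: rule 3 requires j+k <= m
        assert skip_rule(5, 4, 8, [(5, "R"), (6, "D")]) is None


class TestGenFriends:
    def test_full_length_kmer_deletion_neighbors(self):
        nbs = list(gen_friends("ACGT", 1, 4, 3, 1))
        assert sorted(nb.motif for nb in nbs) == ["ACG", "ACT", "AGT", "CGT"]

    def test_interior_short_kmer_keeps_one_insertion(self):
        # "CG" at j=2: the leftmost insertion is covered by the k-mer at j=1
        # and the right-end insertion by the k-mer at j=3
        nbs = list(gen_friends("ACGT", 2, 2, 3, 1))
        assert [nb.motif for nb in nbs] == ["C*G"]

    def test_rightmost_short_kmer_allows_right_end_insertion(self):
        nbs = list(gen_friends("ACGT", 3, 2, 3, 1))
        assert sorted(nb.motif for nb in nbs) == ["G*T", "GT*"]


class TestGenAll:
    def test_reference_enumeration(self):
        nbs = list(gen_all("ACGT", 3, 1))
        assert len(nbs) == 15
        assert sorted(nb.motif for nb in nbs) == sorted(
            ["CGT", "AGT", "ACT", "ACG"]
            + ["*CG", "A*G", "AC*", "*GT", "C*T", "CG*"]
            + ["*AC", "A*C", "C*G", "G*T", "GT*"]
        )

    def test_without_edits_yields_exact_substrings(self):
        nbs = list(gen_all("ACGTAC", 4, 0))
        assert [nb.motif for nb in nbs] == ["ACGT", "CGTA", "GTAC"]
        assert all(len(nb.trace.ops) == 0 for nb in nbs)

    def test_every_trace_has_exactly_d_sorted_operations(self, rand):
        for _ in range(10):
            S = random_dna(rand, rand.randint(6, 14))
            l, d = rand.randint(3, 5), rand.randint(1, 2)
            for nb in gen_all(S, l, d):
                assert len(nb.trace.ops) == d
                assert len(nb.motif) == l
                keys = [(op.p, OP_ORDER[op.o]) for op in nb.trace.ops]
                assert keys == sorted(keys)
                delta, beta, alpha = (
                    nb.trace.deletions,
                    nb.trace.substitutions,
                    nb.trace.insertions,
                )
                assert (delta, beta, alpha) in set(phase_plan(nb.k, l, d))

    def test_longest_kmers_only_delete(self, rand):
        S = random_dna(rand, 12)
        for nb in gen_all(S, 4, 2):
            if nb.k == 6:
                assert all(op.o == "D" for op in nb.trace.ops)

    def test_completeness_against_oracle_with_and_without_rules(self, rand):
        for _ in range(20):
            S = random_dna(rand, rand.randint(5, 20))
            l = rand.randint(3, 5)
            d = rand.randint(0, 2)
            oracle = oracle_motifs_one_string(S, l, d, method="scan")
            for rules in (True, False):
                got = expansions(gen_all(S, l, d, rules_enabled=rules))
                assert got == oracle

    def test_rules_preserve_compact_set_when_string_is_long_enough(self, rand):
        # with m >= l+d the skipped tuples always have a surviving twin
        # producing the same compact string
        for _ in range(15):
            l = rand.randint(3, 5)
            d = rand.randint(1, 2)
            S = random_dna(rand, rand.randint(l + d, l + d + 8))
            on = Counter(nb.motif for nb in gen_all(S, l, d, rules_enabled=True))
            off = Counter(nb.motif for nb in gen_all(S, l, d, rules_enabled=False))
            assert set(on) == set(off)
            assert sum(on.values()) <= sum(off.values())

    def test_duplication_free_on_distinct_characters(self, rand):
        big = Alphabet(tuple(string.ascii_uppercase))
        for _ in range(10):
            m = rand.randint(6, 12)
            S = "".join(rand.sample(string.ascii_uppercase, m))
            l = rand.randint(3, 5)
            d = rand.randint(1, 3)
            if l <= d:
                continue
            counts = Counter(nb.motif for nb in gen_all(S, l, d, alphabet=big))
            assert all(c == 1 for c in counts.values())

    def test_parameter_validation(self):
        with pytest.raises(InvalidParameterError):
            list(gen_all("ACGT", 2, 2))
        with pytest.raises(InvalidParameterError):
            list(gen_friends("ACGT", 4, 3, 3, 1))  # k-mer exceeds the string
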