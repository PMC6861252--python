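"""Statistics against brute-force oracles and closed forms."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invorigin.alignment import AlignmentError, LabeledAlignment
from invorigin.popgen import (
    FstUndefinedError,
    StatisticsError,
    complete_deletion,
    fst_hudson,
    fst_matrix,
    fst_permutation_p,
    jc_correct,
    summarize_polymorphism,
)

from conftest import random_alignment


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation under test)

def brute_pi(seqs):
    pairs = list(itertools.combinations(seqs, 2))
    L = len(seqs[0])
    return sum(sum(a != b for a, b in zip(x, y)) for x, y in pairs) / (len(pairs) * L)


def brute_site_stats(seqs):
    S = singles = multi = 0
    for col in zip(*seqs):
        counts = Counter(col)
        if len(counts) > 1:
            S += 1
            if any(v == 1 for v in counts.values()):
                singles += 1
            if len(counts) > 2:
                multi += 1
    return S, singles, multi


def brute_fst(group_a, group_b):
    L = len(group_a[0])

    def mean_pairwise(pairs):
        return sum(
            sum(a != b for a, b in zip(x, y)) for x, y in pairs
        ) / (len(pairs) * L)

    pi_a = mean_pairwise(list(itertools.combinations(group_a, 2)))
    pi_b = mean_pairwise(list(itertools.combinations(group_b, 2)))
    pi_between = mean_pairwise([(x, y) for x in group_a for y in group_b])
    return 1 - 0.5 * (pi_a + pi_b) / pi_between


# ---------------------------------------------------------------------------

class TestCompleteDeletion:
    def test_gap_free_keeps_all(self):
        aln = LabeledAlignment.from_sequences(["a", "b"], ["ACGT", "ACGA"])
        assert complete_deletion(aln).all()

    def test_single_gap_drops_column(self):
        aln = LabeledAlignment.from_sequences(["a", "b"], ["AC-T", "ACGA"])
        assert list(complete_deletion(aln)) == [True, True, False, True]

    def test_all_gapped_warns_empty(self):
        aln = LabeledAlignment.from_sequences(["a", "b"], ["--", "NN"])
        with pytest.warns(UserWarning):
            mask = complete_deletion(aln)
        assert not mask.any()

    def test_empty_alignment_error(self):
        with pytest.raises(AlignmentError):
            LabeledAlignment.from_sequences([], [])


class TestPolymorphismSummary:
    def test_identical_pair(self):
        aln = LabeledAlignment.from_sequences(["a", "b"], ["ACGT" * 5] * 2)
        s = summarize_polymorphism(aln)
        assert (s.pi, s.S, s.h) == (0.0, 0, 1)

    def test_single_difference_convention(self):
        x = "A" * 100
        y = "A" * 99 + "T"
        s = summarize_polymorphism(LabeledAlignment.from_sequences(["a", "b"], [x, y]))
        assert s.pi == pytest.approx(0.01)
        assert s.S == 1 and s.singletons == 1

    def test_matches_brute_force_on_random_alignments(self, rng):
        for _ in range(5):
            aln = random_alignment(rng, n=5, length=200, p_mut=0.15)
            seqs = [aln.sequence(i) for i in range(5)]
            s = summarize_polymorphism(aln)
            assert s.pi == pytest.approx(brute_pi(seqs))
            S, singles, multi = brute_site_stats(seqs)
            assert (s.S, s.singletons, s.multihit) == (S, singles, multi)
            assert s.h == len(set(seqs))

    def test_gapped_columns_excluded(self, rng):
        aln = random_alignment(rng, n=6, length=120, p_mut=0.1, p_gap=0.05)
        s = summarize_polymorphism(aln)
        mask = complete_deletion(aln)
        sub = [aln.sequence(i) for i in range(6)]
        sub = ["".join(c for c, m in zip(seq, mask) if m) for seq in sub]
        assert s.sites_used == int(mask.sum())
        assert s.pi == pytest.approx(brute_pi(sub))

    def test_divergence_uses_outgroup(self):
        ingroup = ["A" * 100, "A" * 100]
        out = "A" * 91 + "C" * 9  # p = 0.09 to both ingroup sequences
        aln = LabeledAlignment.from_sequences(
            ["a", "b", "og"], ingroup + [out], outgroup_flags=[False, False, True]
        )
        s = summarize_polymorphism(aln)
        assert s.K == pytest.approx(jc_correct(0.09))

    def test_too_few_sequences_error(self):
        aln = LabeledAlignment.from_sequences(["a"], ["ACGT"])
        with pytest.raises(StatisticsError):
            summarize_polymorphism(aln)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_statistics_invariant_under_reordering(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n=6, length=80, p_mut=0.2)
        perm = rng.permutation(6)
        a = summarize_polymorphism(aln)
        b = summarize_polymorphism(aln.take(perm))
        assert a.pi == pytest.approx(b.pi, rel=1e-12)
        assert (a.S, a.singletons, a.multihit, a.h) == (
            b.S, b.singletons, b.multihit, b.h,
        )


class TestJukesCantor:
    def test_closed_form_values(self):
        assert jc_correct(0.0) == 0.0
        assert jc_correct(0.09) == pytest.approx(-0.75 * math.log(1 - 0.12))
        assert jc_correct(0.09) == pytest.approx(0.095875, abs=1e-6)

    def test_saturation_error(self):
        with pytest.raises(StatisticsError):
            jc_correct(0.75)
        with pytest.raises(StatisticsError):
            jc_correct(-0.01)


class TestFst:
    def test_toy_value(self):
        aln = LabeledAlignment.from_sequences(
            ["a1", "a2", "b1", "b2"],
            ["AAAAAAAAAA", "AAAAAAAAAT", "CCCCCAAAAA", "CCCCCAAAAT"],
            regions=["X", "X", "Y", "Y"],
        )
        assert fst_hudson(aln, "X", "Y") == pytest.approx(1 - 0.1 / 0.55)

    def test_fixed_difference_gives_one(self):
        aln = LabeledAlignment.from_sequences(
            ["a1", "a2", "b1", "b2"],
            ["AAAA", "AAAA", "CCCC", "CCCC"],
            regions=["X", "X", "Y", "Y"],
        )
        assert fst_hudson(aln, "X", "Y") == pytest.approx(1.0)

    def test_no_variation_is_undefined(self):
        aln = LabeledAlignment.from_sequences(
            ["a1", "a2", "b1", "b2"], ["AAAA"] * 4, regions=["X", "X", "Y", "Y"]
        )
        with pytest.raises(FstUndefinedError):
            fst_hudson(aln, "X", "Y")

    def test_matches_brute_force_on_random_groups(self, rng):
        for _ in range(5):
            aln = random_alignment(
                rng, n=6, length=100, p_mut=0.2, regions=["X"] * 3 + ["Y"] * 3
            )
            seqs = [aln.sequence(i) for i in range(6)]
            try:
                expected = brute_fst(seqs[:3], seqs[3:])
            except ZeroDivisionError:
                continue
            assert fst_hudson(aln, "X", "Y") == pytest.approx(expected)


class TestPermutationTest:
    def test_strong_differentiation_p_zero(self):
        aln = LabeledAlignment.from_sequences(
            ["a1", "a2", "b1", "b2"],
            ["AAAAAAAAAA", "AAAAAAAAAT", "CCCCCAAAAA", "CCCCCAAAAT"],
            regions=["X", "X", "Y", "Y"],
        )
        res = fst_permutation_p(aln, ["X", "X", "Y", "Y"], n_perm=10000, seed=1)
        assert res.p_value == 0.0
        assert res.fst == pytest.approx(1 - 0.1 / 0.55)

    def test_invalid_n_perm(self):
        aln = LabeledAlignment.from_sequences(
            ["a", "b", "c", "d"], ["ACGT"] * 4, regions=["X", "X", "Y", "Y"]
        )
        with pytest.raises(StatisticsError):
            fst_permutation_p(aln, ["X", "X", "Y", "Y"], n_perm=0, seed=1)

    def test_reproducible_given_seed(self, rng):
        aln = random_alignment(rng, n=8, length=120, p_mut=0.1,
                               regions=["X"] * 4 + ["Y"] * 4)
        a = fst_permutation_p(aln, aln.regions, n_perm=300, seed=7)
        b = fst_permutation_p(aln, aln.regions, n_perm=300, seed=7)
        assert a == b

    def test_null_rejection_rate_near_alpha(self):
        """Panmictic null: ~5% of trials reject at alpha = 0.05.

        Group sizes are unequal (8 v 5), as in the study's comparisons; with
        equal sizes Hudson's F_ST degenerates to a monotone function of the
        integer within-group difference sum and the permutation distribution
        is massively tied.
        """
        rejections = 0
        n_trials = 200
        master = np.random.default_rng(777)
        for _ in range(n_trials):
            aln = random_alignment(master, n=13, length=300, p_mut=0.05,
                                   regions=["X"] * 8 + ["Y"] * 5)
            seed = int(master.integers(2**31))
            res = fst_permutation_p(aln, aln.regions, n_perm=400, seed=seed)
            if res.p_value < 0.05:
                rejections += 1
        rate = rejections / n_trials
        assert 0.025 <= rate <= 0.075


class TestFstMatrix:
    def test_two_groups_single_entry(self, rng):
        aln = random_alignment(rng, n=6, length=100, p_mut=0.15,
                               regions=["X"] * 3 + ["Y"] * 3)
        m = fst_matrix(aln, n_perm=50, seed=1)
        assert m.fst.shape == (2, 2)
        assert np.isnan(m.fst.loc["X", "X"])
        assert m.fst.loc["X", "Y"] == m.fst.loc["Y", "X"]

    def test_matches_elementwise_recomputation(self, rng):
        aln = random_alignment(rng, n=9, length=150, p_mut=0.15,
                               regions=["X"] * 3 + ["Y"] * 3 + ["Z"] * 3)
        m = fst_matrix(aln, n_perm=50, seed=1)
        for a, b in itertools.combinations(["X", "Y", "Z"], 2):
            assert m.fst.loc[a, b] == pytest.approx(fst_hudson(aln, a, b))

    def test_single_group_error(self, rng):
        aln = random_alignment(rng, n=4, length=50, p_mut=0.1)
        with pytest.raises(StatisticsError):
            fst_matrix(aln, n_perm=10, seed=1)
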