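"""Population differentiation statistics against brute-force oracles,
exhaustive permutation enumeration, and island-model expectations."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from rp1sweep.alignio import LocusAlignment, SequenceRecord
from rp1sweep.differentiation import (
    differentiation_suite,
    hudson_fst,
    nm_from_fst,
    nst_minus_gst,
    permute_labels_test,
    phylogeography_flag,
)
from rp1sweep.simdata import island_model_dataset

from conftest import make_alignment, random_alignment


def aln_from(seqs, pop, prefix):
    recs = [
        SequenceRecord(f"{prefix}{i}", pop, "r", s) for i, s in enumerate(seqs)
    ]
    return LocusAlignment("test", recs)


def brute_fst(seqs_a, seqs_b):
    """Oracle: 1 - Hw/Hb by full pair enumeration, per site."""
    L = len(seqs_a[0])

    def within(seqs):
        n = len(seqs)
        tot = sum(
            sum(x != y for x, y in zip(a, b))
            for a, b in combinations(seqs, 2)
        )
        return tot / comb(n, 2) / L

    hw = (within(seqs_a) + within(seqs_b)) / 2
    hb = sum(
        sum(x != y for x, y in zip(a, b)) for a in seqs_a for b in seqs_b
    ) / (len(seqs_a) * len(seqs_b)) / L
    return 1 - hw / hb if hb else None


def brute_kst(seqs_a, seqs_b):
    """Oracle: 1 - KS/KT with sample-size-weighted within term."""

    def mean_within(seqs):
        n = len(seqs)
        if n < 2:
            return 0.0
        return sum(
            sum(x != y for x, y in zip(a, b))
            for a, b in combinations(seqs, 2)
        ) / comb(n, 2)

    na, nb = len(seqs_a), len(seqs_b)
    ks = (na * mean_within(seqs_a) + nb * mean_within(seqs_b)) / (na + nb)
    kt = mean_within(seqs_a + seqs_b)
    return 1 - ks / kt if kt else None


class TestHudsonFst:
    def test_two_samples_of_one_population_give_near_zero(self):
        rng = np.random.default_rng(0)
        pool = random_alignment(rng, 12, 60)
        seqs = [r.sequence for r in pool.records]
        a = aln_from(seqs[:6], "A", "a")
        b = aln_from(seqs[6:], "B", "b")
        fst, hw, hb = hudson_fst(a, b)
        assert abs(fst) < 0.35  # exchangeable split, noisy but small
        assert hw > 0 and hb > 0

    def test_fixed_differences_give_fst_one(self):
        a = aln_from(["AAAA"] * 4, "A", "a")
        b = aln_from(["AAGA"] * 4, "B", "b")
        fst, hw, hb = hudson_fst(a, b)
        assert fst == pytest.approx(1.0)
        assert hw == 0.0

    def test_identical_monomorphic_populations_are_undefined(self):
        a = aln_from(["AAAA"] * 3, "A", "a")
        b = aln_from(["AAAA"] * 3, "B", "b")
        fst, _, hb = hudson_fst(a, b)
        assert fst is None and hb == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seqs_a = [r.sequence for r in random_alignment(rng, 6, 30).records]
        seqs_b = [r.sequence for r in random_alignment(rng, 6, 30).records]
        a, b = aln_from(seqs_a, "A", "a"), aln_from(seqs_b, "B", "b")
        fst, _, _ = hudson_fst(a, b)
        assert fst == pytest.approx(brute_fst(seqs_a, seqs_b), abs=1e-12)

    def test_symmetric_in_population_order(self):
        rng = np.random.default_rng(9)
        a = aln_from(
            [r.sequence for r in random_alignment(rng, 5, 40).records],
            "A", "a")
        b = aln_from(
            [r.sequence for r in random_alignment(rng, 7, 40).records],
            "B", "b")
        assert hudson_fst(a, b)[0] == pytest.approx(hudson_fst(b, a)[0])
        for x, y in zip(differentiation_suite(a, b),
                        differentiation_suite(b, a)):
            assert x == pytest.approx(y)


class TestNm:
    @pytest.mark.parametrize(
        "fst,expected",
        [(0.5, 0.25), (0.0225, 10.86), (1.0, 0.0)],
    )
    def test_island_model_conversion(self, fst, expected):
        assert round(nm_from_fst(fst), 2) == expected

    def test_undefined_at_or_below_zero(self):
        assert nm_from_fst(0.0) is None
        assert nm_from_fst(-0.1) is None
        assert nm_from_fst(None) is None


class TestDifferentiationSuite:
    def test_random_split_of_pooled_sample_near_zero(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(30):
            pool = random_alignment(rng, 12, 50)
            seqs = [r.sequence for r in pool.records]
            idx = rng.permutation(12)
            a = aln_from([seqs[i] for i in idx[:6]], "A", "a")
            b = aln_from([seqs[i] for i in idx[6:]], "B", "b")
            gst, hst, kst, nst = differentiation_suite(a, b)
            defined = [v for v in (gst, hst, kst, nst) if v is not None]
            if defined:
                vals.append(defined)
        means = np.mean([np.mean(v) for v in vals])
        assert abs(means) < 0.1  # exchangeability: ~0 in expectation

    def test_two_fixed_haplotypes_maximal_structure(self):
        a = aln_from(["AAAA"] * 5, "A", "a")
        b = aln_from(["GGAA"] * 5, "B", "b")
        gst, hst, kst, nst = differentiation_suite(a, b)
        assert kst == pytest.approx(1.0 - 0.0)  # no within variation
        assert gst > 0.4 and hst > 0.4
        assert nst == pytest.approx(1.0)

    def test_kst_matches_bruteforce_4_plus_4(self):
        rng = np.random.default_rng(11)
        seqs_a = [r.sequence for r in random_alignment(rng, 4, 25).records]
        seqs_b = [r.sequence for r in random_alignment(rng, 4, 25).records]
        a, b = aln_from(seqs_a, "A", "a"), aln_from(seqs_b, "B", "b")
        _, _, kst, _ = differentiation_suite(a, b)
        assert kst == pytest.approx(brute_kst(seqs_a, seqs_b), abs=1e-12)

    def test_nst_exceeds_gst_with_related_haplotypes(self):
        """Phylogeographic toy set: population A's two haplotypes are
        one step apart, population B's haplotype is far from both; the
        distance-aware statistic must exceed the identity-based one."""
        a = aln_from(["AAAAAAAA"] * 3 + ["AAAAAAAC"] * 3, "A", "a")
        b = aln_from(["GGGGGGGG"] * 3 + ["GGGGGGGC"] * 3, "B", "b")
        gst, _, _, nst = differentiation_suite(a, b)
        assert nst > gst


class TestPermutationTest:
    def test_identical_populations_give_high_p(self):
        a = aln_from(["ACGT"] * 4, "A", "a")
        b = aln_from(["ACGT"] * 4, "B", "b")
        _, p = permute_labels_test(
            lambda x, y: differentiation_suite(x, y)[2], a, b,
            n_perms=100, seed=0,
        )
        assert p is None  # KT = 0: statistic undefined on identical data

    def test_exhaustive_3_plus_3_enumeration(self):
        """Sampled permutation p within Monte-Carlo error of the exact
        p over all C(6,3)=20 label splits."""
        seqs = ["AAAA", "AAAG", "AAGG", "GGGG", "GGGA", "GGAA"]
        a, b = aln_from(seqs[:3], "A", "a"), aln_from(seqs[3:], "B", "b")

        def kst_fn(x, y):
            return differentiation_suite(x, y)[2]

        observed = kst_fn(a, b)
        exact_ge = 0
        from itertools import combinations as icombs

        for split in icombs(range(6), 3):
            ga = [seqs[i] for i in split]
            gb = [seqs[i] for i in range(6) if i not in split]
            val = kst_fn(aln_from(ga, "A", "a"), aln_from(gb, "B", "b"))
            if val is not None and val >= observed:
                exact_ge += 1
        exact_p = exact_ge / 20
        _, p = permute_labels_test(kst_fn, a, b, n_perms=2000, seed=3)
        assert p == pytest.approx(exact_p, abs=0.05)

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(8)
        a = aln_from(
            [r.sequence for r in random_alignment(rng, 4, 20).records],
            "A", "a")
        b = aln_from(
            [r.sequence for r in random_alignment(rng, 4, 20).records],
            "B", "b")
        fn = lambda x, y: differentiation_suite(x, y)[2]
        assert permute_labels_test(fn, a, b, 200, seed=5) == \
            permute_labels_test(fn, a, b, 200, seed=5)


class TestPhylogeographyFlag:
    def test_equal_statistics_not_flagged(self):
        assert phylogeography_flag(0.3, 0.3, 0.01) is False

    def test_structured_data_flagged(self):
        a = aln_from(["AAAAAAAA"] * 3 + ["AAAAAAAC"] * 3, "A", "a")
        b = aln_from(["GGGGGGGG"] * 3 + ["GGGGGGGC"] * 3, "B", "b")
        gst, _, _, nst = differentiation_suite(a, b)
        _, p = permute_labels_test(nst_minus_gst, a, b, 500, seed=2)
        assert phylogeography_flag(nst, gst, p) is True

    def test_panmictic_simulation_rarely_flagged(self):
        rng = np.random.default_rng(21)
        flagged = 0
        reps = 40
        for _ in range(reps):
            pool = island_model_dataset(2, 6, 3.0, 100.0, seed=rng, L=300)
            pops = pool.by_population()
            a, b = pops["pop1"], pops["pop2"]
            gst, _, _, nst = differentiation_suite(a, b)
            if gst is None or nst is None:
                continue
            _, p = permute_labels_test(nst_minus_gst, a, b, 99, seed=rng)
            if phylogeography_flag(nst, gst, p):
                flagged += 1
        assert flagged <= max(1, int(0.05 * reps) + 2)
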