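import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from cenland.core_io import GenomicInterval
from cenland.synthetic_data import random_dna
from cenland.te_dating import (
    LTRElement,
    aligned_identity,
    assign_compartment,
    centromere_composition,
    date_element,
    divergence,
    insertion_time,
    wilcoxon_rank_sum,
)


class TestAlignedIdentity:
    def test_identical(self):
        s = "ACGT" * 25
        assert aligned_identity(s, s) == 100.0

    def test_one_mismatch_in_100(self):
        a = "A" * 100
        b = "A" * 50 + "C" + "A" * 49
        assert aligned_identity(a, b) == pytest.approx(99.0)

    def test_deletion_gap_columns_non_identical(self):
        a = "A" * 50 + "C" * 50
        b = "A" * 50 + "C" * 48  # 2-bp deletion
        # 98 identical pairs over 100 alignment columns
        assert aligned_identity(a, b) == pytest.approx(100 * 98 / 100)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            aligned_identity("", "ACGT")


class TestDivergence:
    def test_identical_zero_under_all_models(self):
        s = "ATGCATGCAT" * 10
        for model in ("raw", "JC69", "K80"):
            assert divergence(s, s, model) == pytest.approx(0.0)

    def test_k80_transitions_closed_form(self):
        # 2% mismatches, all transitions (A<->G): K80 = -0.5 ln(0.96)
        a = "AC" * 50
        b = "GC" * 1 + "AC" * 49  # 1 A->G in 100 sites
        b = ("GC" + "AC" * 49)[:100]
        a = "AC" * 50
        # build 2 transitions in 100 sites
        a = "A" * 100
        b = "G" * 2 + "A" * 98
        k = divergence(a, b, "K80")
        assert k == pytest.approx(-0.5 * math.log(1 - 2 * 0.02), rel=1e-9)

    def test_jc69_closed_form(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90  # p = 0.10
        k = divergence(a, b, "JC69")
        assert k == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), rel=1e-9)

    def test_models_agree_at_small_p(self):
        n = 10_000
        a = "A" * n
        b = "C" + "A" * (n - 1)  # p = 1e-4
        raw = divergence(a, b, "raw")
        jc = divergence(a, b, "JC69")
        assert abs(jc - raw) / raw < 2e-4

    def test_saturation_error(self):
        a = "A" * 100
        b = "C" * 100
        with pytest.raises(ValueError, match="saturated"):
            divergence(a, b, "JC69")


class TestInsertionTime:
    def test_zero(self):
        assert insertion_time(0.0) == 0.0

    def test_printed_formula(self):
        assert insertion_time(0.005, 2.5e-9) == pytest.approx(1.0e6)
        assert insertion_time(0.025, 2.5e-9) == pytest.approx(5.0e6)

    def test_linear_in_k_inverse_in_r(self, rng):
        for _ in range(20):
            k = rng.uniform(0, 0.2)
            r = rng.uniform(1e-10, 1e-8)
            c = rng.uniform(0.1, 10)
            assert insertion_time(c * k, r) == pytest.approx(c * insertion_time(k, r))
            assert insertion_time(k, c * r) == pytest.approx(insertion_time(k, r) / c)

    def test_bad_rate_error(self):
        with pytest.raises(ValueError):
            insertion_time(0.01, 0)


def exact_two_sided_p(x, y):
    """Independent exhaustive-permutation oracle (tie-free inputs)."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n, N = len(x), len(x) + len(y)
    mu = n * (N + 1) / 2
    w_obs = sum(ranks[v] for v in x)
    count = total = 0
    for comb in combinations(pooled, n):
        total += 1
        w = sum(ranks[v] for v in comb)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestWilcoxonRankSum:
    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_extreme_separation_small_n(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert stat == 6.0
        assert p == pytest.approx(0.1)

    def test_two_vs_two(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_matches_exhaustive_permutation_sweep(self, rng):
        """All tie-free inputs with n+m <= 10 (random values, all splits)."""
        for n in range(1, 6):
            for m in range(1, 11 - n):
                vals = rng.normal(size=n + m)
                while len(set(vals)) < n + m:
                    vals = rng.normal(size=n + m)
                x, y = list(vals[:n]), list(vals[n:])
                _, p = wilcoxon_rank_sum(x, y)
                assert p == pytest.approx(exact_two_sided_p(x, y))

    def test_normal_approximation_close_to_scipy(self, rng):
        x = list(rng.normal(size=40))
        y = list(rng.normal(0.6, size=35))
        _, p = wilcoxon_rank_sum(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=0.05)

    def test_ties_handled_with_midranks(self):
        _, p = wilcoxon_rank_sum([1, 1, 2, 2] * 6, [1, 2, 2, 3] * 6)
        assert 0 < p <= 1

    def test_non_finite_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0, float("nan")], [2.0])


def elem(chrom, start, end, ltr_len=100, family="CRM"):
    return LTRElement(
        element=GenomicInterval(chrom, start, end),
        family=family,
        ltr5=GenomicInterval(chrom, start, start + ltr_len),
        ltr3=GenomicInterval(chrom, end - ltr_len, end),
    )


class TestCompartment:
    def test_midpoint_rule(self):
        cen = [GenomicInterval("c", 10_000, 20_000)]
        inside = elem("c", 12_000, 14_000)
        straddle = elem("c", 19_500, 25_000)  # midpoint 22250 outside
        outside = elem("c", 50_000, 52_000)
        other_chrom = elem("d", 12_000, 14_000)
        out = assign_compartment([inside, straddle, outside, other_chrom], cen)
        assert [e.compartment for e in out] == [
            "centromeric",
            "non_centromeric",
            "non_centromeric",
            "non_centromeric",
        ]


class TestDateElement:
    def test_planted_divergence_dated(self, rng):
        ltr = random_dna(1000, rng)
        mutated = list(ltr)
        for i in range(0, 1000, 100):  # 10 substitutions -> p = 0.01
            mutated[i] = {"A": "G", "G": "A", "C": "T", "T": "C"}[mutated[i]]
        genome = {"c": ltr + "N" * 0 + random_dna(500, rng) + "".join(mutated)}
        e = elem("c", 0, 2500, ltr_len=1000)
        date_element(e, genome, model="raw")
        assert e.K == pytest.approx(0.01)
        assert e.T == pytest.approx(insertion_time(0.01))
        assert e.identity == pytest.approx(99.0)


class TestComposition:
    def test_single_annotation_fraction(self):
        cen = GenomicInterval("c", 0, 100_000)
        tes = [(GenomicInterval("c", 20_000, 60_000), "CRM")]
        rep = centromere_composition(tes, [cen])[0]
        assert rep.family_percent["CRM"] == pytest.approx(40.0)
        assert rep.repeat_percent == pytest.approx(40.0)

    def test_no_annotations_zero(self):
        rep = centromere_composition([], [GenomicInterval("c", 0, 1000)])[0]
        assert rep.repeat_percent == 0.0
        assert all(v == 0 for v in rep.family_percent.values())

    def test_duplicate_intervals_counted_once(self):
        cen = GenomicInterval("c", 0, 1000)
        tes = [(GenomicInterval("c", 100, 200), "CRM")] * 2
        rep = centromere_composition(tes, [cen])[0]
        assert rep.family_percent["CRM"] == pytest.approx(10.0)

    def test_longer_annotation_priority(self):
        cen = GenomicInterval("c", 0, 1000)
        tes = [
            (GenomicInterval("c", 0, 500), "ATHILA"),
            (GenomicInterval("c", 400, 600), "CRM"),  # shorter, loses overlap
        ]
        rep = centromere_composition(tes, [cen])[0]
        assert rep.family_percent["ATHILA"] == pytest.approx(50.0)
        assert rep.family_percent["CRM"] == pytest.approx(10.0)
        assert rep.repeat_percent == pytest.approx(60.0)

    def test_clipping_to_centromere(self):
        cen = GenomicInterval("c", 1000, 2000)
        tes = [(GenomicInterval("c", 0, 1500), "LINE")]
        rep = centromere_composition(tes, [cen])[0]
        assert rep.family_percent["LINE"] == pytest.approx(50.0)

    def test_overall_at_least_each_family(self, rng):
        cen = GenomicInterval("c", 0, 50_000)
        tes = []
        for _ in range(20):
            s = int(rng.integers(0, 49_000))
            e = s + int(rng.integers(100, 2000))
            tes.append(
                (GenomicInterval("c", s, min(e, 50_000)),
                 str(rng.choice(["CRM", "ATHILA", "LINE", "other"])))
            )
        rep = centromere_composition(tes, [cen])[0]
        assert rep.repeat_percent <= 100
        assert all(rep.repeat_percent >= v - 1e-9 for v in rep.family_percent.values())
        assert sum(rep.family_percent.values()) == pytest.approx(rep.repeat_percent)
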