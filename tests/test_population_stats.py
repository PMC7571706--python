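"""Population statistics: overlap, diversity, robustness, spectra, evolvability."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tfscape as t


class TestOverlap:
    def test_worked_example(self):
        # |C| = |{1,2,2}| = 3, min(|A|,|B|) = 4 -> 0.75
        assert t.overlap({1: 2, 2: 3, 3: 1}, {1: 1, 2: 2, 4: 1}) == 0.75

    def test_identical_and_disjoint(self):
        a = {"x": 3, "y": 2}
        assert t.overlap(a, a) == 1.0
        assert t.overlap(a, {"z": 5}) == 0.0

    def test_accepts_iterables(self):
        assert t.overlap([1, 1, 2, 2, 2, 3], [1, 2, 2, 4]) == 0.75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            t.overlap({}, {"a": 1})

    @given(st.dictionaries(st.integers(0, 5), st.integers(1, 10), min_size=1),
           st.dictionaries(st.integers(0, 5), st.integers(1, 10), min_size=1))
    @settings(derandomize=True)
    def test_symmetric_bounded(self, a, b):
        o = t.overlap(a, b)
        assert o == t.overlap(b, a)
        assert 0 <= o <= 1


class TestShannonDiversity:
    def test_monomorphic_is_zero(self):
        assert t.shannon_diversity({"AAAAAAAA": 500}, n=100) == 0.0

    def test_uniform_over_landscape_is_one(self):
        pop = {f"g{i}": 7 for i in range(64)}
        assert t.shannon_diversity(pop, n=64) == pytest.approx(1.0)

    def test_two_of_four(self):
        pop = {"a": 50, "b": 50}
        assert t.shannon_diversity(pop, n=4) == pytest.approx(0.5)

    def test_requires_n_at_least_two(self):
        with pytest.raises(ValueError):
            t.shannon_diversity({"a": 1}, n=1)

    def test_spreading_a_copy_increases_diversity(self):
        # move one copy from the most to the least frequent genotype
        before = {"a": 90, "b": 9, "c": 1}
        after = {"a": 89, "b": 9, "c": 2}
        assert (t.shannon_diversity(after, 50)
                > t.shannon_diversity(before, 50))


class TestNucleotideDiversity:
    def test_monomorphic_is_zero(self):
        assert t.nucleotide_diversity({"AAAAAAAA": 10}) == 0.0

    def test_one_site_fifty_fifty(self):
        pop = {"AAAAAAAA": 50, "AAAAAAAC": 50}
        # ordered double sum: 2 * 0.5 * 0.5 * (1/8)
        assert t.nucleotide_diversity(pop) == pytest.approx(0.0625)

    def test_matches_hand_double_sum_on_small_multisets(self):
        pop = {"AAAAAAAA": 2, "AAAAAAAC": 1, "AAAAACCC": 1}
        gens = list(pop)
        N = sum(pop.values())
        expected = sum(
            (pop[x] / N) * (pop[y] / N) * t.strand_distance(x, y) / 8
            for x in gens for y in gens)
        assert t.nucleotide_diversity(pop) == pytest.approx(expected, rel=1e-12)
        assert t.nucleotide_diversity(pop, corrected=True) == pytest.approx(
            expected * N / (N - 1), rel=1e-12)

    def test_strand_symmetric(self):
        pop = {"AAAAAAAC": 30, "AAAAAACC": 70}
        flipped = {t.canonical(t.revcomp(g)): c for g, c in pop.items()}
        assert t.nucleotide_diversity(pop) == pytest.approx(
            t.nucleotide_diversity(flipped))


class TestRobustness:
    def test_fully_embedded_genotype(self):
        scores = {"AAAAAAAA": 0.40}
        for nb, _ in t.neighbors("AAAAAAAA"):
            scores[nb] = 0.36
        L = t.build_landscape(t.ScoreTable(tf_name="ball", scores=scores),
                              min_component=25)
        assert t.robustness("AAAAAAAA", L) == 1.0

    def test_partial_neighborhood(self):
        scores = {"AAAAAAAA": 0.40}
        kept = [nb for nb, _ in t.neighbors("AAAAAAAA")][:6]
        for nb in kept:
            scores[nb] = 0.36
        L = t.build_landscape(t.ScoreTable(tf_name="six", scores=scores),
                              min_component=7)
        assert t.robustness("AAAAAAAA", L) == pytest.approx(6 / 24)

    def test_mean_robustness_consistent_with_edge_count(self):
        # sum of |neighbors in L| over nodes = 2|E| when no genotype pair is
        # double-counted, so mean robustness = 2|E| / (24 n) off palindromes
        L = t.synthesize(t.SynthConfig(target_bound_size=100, seed=2))
        if any(t.is_palindrome(g) for g in L.genotypes):
            pytest.skip("palindromes change the denominator")
        mean_rob = np.mean([t.robustness(g, L) for g in L.genotypes])
        assert mean_rob == pytest.approx(2 * len(L.edges) / (24 * L.n))

    def test_not_in_landscape_rejected(self, fork):
        with pytest.raises(ValueError):
            t.robustness("CCCCCCCC", fork)

    def test_population_mean_weighted_by_counts(self, fork):
        pop = {"AAAAAAAA": 3, "GAAAAAAA": 1}
        r0 = t.robustness("AAAAAAAA", fork)
        r1 = t.robustness("GAAAAAAA", fork)
        assert t.population_robustness(pop, fork) == pytest.approx(
            (3 * r0 + r1) / 4)


class TestAlleleSpectrum:
    def test_monomorphic_at_reference_is_empty(self):
        res = t.allele_spectrum({"AAAAAAAA": 100}, "AAAAAAAA")
        assert res.entries.empty
        assert res.reference_freq == 1.0
        assert res.multi_hit_freq == 0.0

    def test_single_transition_polymorphism(self):
        res = t.allele_spectrum({"AAAAAAAA": 90, "GAAAAAAA": 10}, "AAAAAAAA")
        assert len(res.entries) == 1
        row = res.entries.iloc[0]
        assert (row.position, row.ref, row.alt) == (1, "A", "G")
        assert row.mclass == t.TRANSITION
        assert row.freq == pytest.approx(0.1)

    def test_frequencies_partition_to_one(self):
        pop = {"AAAAAAAA": 70, "GAAAAAAA": 10, "CAAAAAAA": 5, "GGAAAAAA": 15}
        res = t.allele_spectrum(pop, "AAAAAAAA")
        total = res.reference_freq + res.entries.freq.sum() + res.multi_hit_freq
        assert total == pytest.approx(1.0)
        assert res.multi_hit_freq == pytest.approx(0.15)

    def test_orientation_minimizes_distance(self):
        # population genotype stored on the opposite strand of the reference
        ref = "CTGCTAAA"
        other = t.canonical("CTGCTAAC")  # one substitution on ref orientation
        res = t.allele_spectrum({other: 10, t.canonical(ref): 90}, ref)
        assert len(res.entries) == 1
        assert res.entries.iloc[0].position == 8


class TestEvolvability:
    def _landscape(self, center, score=0.4):
        scores = {center: score}
        for nb, _ in t.neighbors(center):
            scores[nb] = 0.36
        return t.build_landscape(
            t.ScoreTable(tf_name=f"L_{center}", scores=scores), min_component=2)

    def test_counts_landscapes_reached_by_one_mutants(self):
        focal = self._landscape("AAAAAAAA")
        near = self._landscape("AAAAACCC")   # shares one-mutant neighbors? no:
        # neighbors of focal population reach sequences at distance <= 2 of
        # AAAAAAAA; AAAAACCC's ball is centered 3 away but its own one-ball
        # reaches distance-2 sequences of AAAAAAAA? center distance 3, so its
        # members lie at distance >= 2: overlap exists at exactly distance 2.
        far = self._landscape("CCGGCCGG")
        pop = {"AAAAAAAA": 10}
        frac, count = t.evolvability(pop, focal, [near, far])
        assert count in (0, 1, 2)
        # distance argument: one-mutants of AAAAAAAA lie within distance 1;
        # members of far lie within 1 of CCGGCCGG (distance 8 away): disjoint
        novel = {nb for nb, _ in t.neighbors("AAAAAAAA")}
        expected = sum(1 for L in (near, far)
                       if any(nb in L.index for nb in novel))
        assert count == expected
        assert frac == pytest.approx(count / 2)

    def test_focal_must_be_excluded(self):
        focal = self._landscape("AAAAAAAA")
        with pytest.raises(ValueError):
            t.evolvability({"AAAAAAAA": 1}, focal, [focal])

    def test_adding_empty_landscape_lowers_fraction_keeps_count(self):
        focal = self._landscape("AAAAAAAA")
        near = self._landscape("AAAAAAAC", score=0.45)
        far = self._landscape("CCGGCCGG")
        # population sits on the focal boundary so some one-mutants are novel
        pop = {"AAAAAAAC": 5}
        frac1, count1 = t.evolvability(pop, focal, [near])
        assert count1 >= 1
        frac2, count2 = t.evolvability(pop, focal, [near, far])
        assert count2 == count1
        assert frac2 < frac1

    def test_synthetic_collection_end_to_end(self):
        coll = t.generate_collection(3, t.SynthConfig(target_bound_size=100,
                                                      seed=31))
        focal, rest = coll[0], coll[1:]
        pop = {focal.peak: 100}
        frac, count = t.evolvability(pop, focal, rest)
        assert 0 <= frac <= 1 and count == round(frac * len(rest))
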