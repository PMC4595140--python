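"""Synteny index: neighborhoods, SI, average SI, cutoffs, recipients."""
import random

import pytest
from hypothesis import given, settings, strategies as st

from nearhgt.errors import GeneNotInGenomeError, NoSharedGenesError
from nearhgt.synteny import (
    Genome,
    SIProfile,
    average_si,
    infer_recipient,
    neighborhood,
    si_candidates,
    si_cutoff,
    si_histogram,
    si_profile,
    synteny_index,
)


def brute_force_si(gene, g1, g2, k):
    """Independent oracle: scan positions directly, intersect name sets."""
    def nbhd(genome):
        if gene not in genome.positions:
            return None
        pos = genome.positions[gene]
        n = len(genome)
        names = set()
        for off in list(range(-k, 0)) + list(range(1, k + 1)):
            i = pos + off
            if genome.topology == "circular":
                names.add(genome.genes[i % n])
            elif 0 <= i < n:
                names.add(genome.genes[i])
        names.discard(gene)
        return names

    n1, n2 = nbhd(g1), nbhd(g2)
    if n1 is None or n2 is None:
        return 0
    return len(n1 & n2)


class TestNeighborhood:
    def test_circular_full_window(self):
        g = Genome("G", tuple(f"g{i}" for i in range(25)))
        assert len(neighborhood(g, "g0", 10)) == 20

    def test_circular_wraparound_saturates_at_n_minus_1(self):
        g = Genome("G", tuple("abcde"))
        assert neighborhood(g, "a", 3) == frozenset("bcde")

    def test_linear_truncates_at_ends(self):
        g = Genome("G", tuple("abcd"), topology="linear")
        assert neighborhood(g, "a", 2) == frozenset("bc")
        assert neighborhood(g, "d", 2) == frozenset("bc")

    def test_absent_gene_raises(self):
        g = Genome("G", tuple("abcd"))
        with pytest.raises(GeneNotInGenomeError):
            neighborhood(g, "z", 2)

    def test_duplicates_canonicalized_to_first_occurrence(self):
        g = Genome("G", ("a", "b", "a", "c"))
        assert g.genes == ("a", "b", "c")
        assert g.dropped_duplicates == ("a",)


class TestSyntenyIndex:
    def test_absent_gene_is_zero(self, toy_pair):
        g1, g2 = toy_pair
        assert synteny_index("d", g1, g2, 2) == 0  # d only in G1
        assert synteny_index("zz", g1, g2, 2) == 0

    def test_identical_genomes_hit_maximum(self):
        g = Genome("G", tuple(f"g{i}" for i in range(25)))
        h = Genome("H", g.genes)
        assert all(synteny_index(x, g, h, 10) == 20 for x in g.genes)

    def test_toy_pair_matches_enumeration_oracle(self, toy_pair):
        g1, g2 = toy_pair
        for gene in set(g1.genes) | set(g2.genes):
            assert synteny_index(gene, g1, g2, 2) == brute_force_si(gene, g1, g2, 2)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_and_bounded_on_random_permutations(self, seed):
        rnd = random.Random(seed)
        names = [f"g{i}" for i in range(12)]
        perm = names[:]
        rnd.shuffle(perm)
        g1, g2 = Genome("A", tuple(names)), Genome("B", tuple(perm))
        k = rnd.randint(1, 4)
        for gene in names:
            si = synteny_index(gene, g1, g2, k)
            assert 0 <= si <= 2 * k
            assert si == synteny_index(gene, g2, g1, k)
            assert si == brute_force_si(gene, g1, g2, k)


class TestAverageSI:
    def test_identical_genomes_give_exactly_one(self):
        g = Genome("G", tuple(f"g{i}" for i in range(25)))
        assert average_si(g, Genome("H", g.genes), 10) == 1.0

    def test_disjoint_genomes_give_exactly_zero(self):
        g1 = Genome("A", tuple("abc"))
        g2 = Genome("B", tuple("xyz"))
        assert average_si(g1, g2, 2) == 0.0

    def test_partial_overlap_matches_hand_computation(self):
        # shared a,b,c in same local order; d,e,f vs x,y,z private
        g1 = Genome("A", tuple("abcdef"))
        g2 = Genome("B", tuple("abcxyz"))
        k = 1
        union = set("abcdefxyz")
        total = sum(brute_force_si(g, g1, g2, k) for g in union)
        assert average_si(g1, g2, k) == pytest.approx(total / (2 * k * len(union)))


def make_profile(si_map, k=10):
    return SIProfile(("A", "B"), k, dict(si_map), frozenset(si_map))


def brute_force_cutoff(si_values, delta):
    """Count-and-check over every observed SI value."""
    n = len(si_values)
    best = -1
    for c in sorted(set(si_values)):
        if sum(v <= c for v in si_values) / n < delta:
            best = c
    return best


class TestCutoffAndCandidates:
    def test_no_low_tail_gives_minus_one(self):
        prof = make_profile({f"g{i}": 20 for i in range(100)})
        assert si_cutoff(prof, 0.05) == -1
        assert si_candidates(prof, 0.05).candidates == ()

    def test_four_of_hundred_low_genes_selected(self):
        si = {f"g{i}": 0 if i < 4 else 20 for i in range(100)}
        prof = make_profile(si)
        assert si_cutoff(prof, 0.05) == 0
        cand = si_candidates(prof, 0.05)
        assert cand.candidates == ("g0", "g1", "g2", "g3")

    def test_six_of_hundred_exceeds_threshold(self):
        si = {f"g{i}": 0 if i < 6 else 20 for i in range(100)}
        assert si_cutoff(make_profile(si), 0.05) == -1

    def test_empty_core_raises(self):
        prof = SIProfile(("A", "B"), 10, {"g": 0}, frozenset())
        with pytest.raises(NoSharedGenesError):
            si_cutoff(prof, 0.05)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_oracle_on_random_profiles(self, seed):
        rnd = random.Random(seed)
        n = rnd.randint(5, 200)
        si = {f"g{i}": rnd.randint(0, 20) for i in range(n)}
        delta = rnd.uniform(0.01, 0.5)
        prof = make_profile(si)
        cutoff = si_cutoff(prof, delta)
        assert cutoff == brute_force_cutoff(list(si.values()), delta)
        cand = si_candidates(prof, delta)
        assert set(cand.candidates) == {g for g, v in si.items() if v <= cutoff}
        # candidate fraction stays below the threshold
        assert len(cand.candidates) / n < delta


class TestHistogram:
    def test_identical_genomes_concentrate_at_2k(self):
        g = Genome("G", tuple(f"g{i}" for i in range(25)))
        prof = si_profile(g, Genome("H", g.genes), 10)
        assert si_histogram(prof) == {**{v: 0 for v in range(21)}, 20: 25}

    def test_disjoint_genomes_concentrate_at_zero(self):
        prof = si_profile(Genome("A", tuple("abc")), Genome("B", tuple("xyz")), 2)
        hist = si_histogram(prof)
        assert hist[0] == 6 and sum(hist.values()) == 6

    def test_union_histogram_sums_to_union_and_core_to_core(self, toy_pair):
        prof = si_profile(*toy_pair, 2)
        assert sum(si_histogram(prof, "union").values()) == len(prof.si)
        assert sum(si_histogram(prof, "core").values()) == len(prof.core_genes)


class TestRelocation:
    def test_relocated_gene_drops_to_zero_and_distant_genes_unchanged(self):
        k = 3
        genes = [f"g{i}" for i in range(40)]
        moved = genes[5]
        reordered = [g for g in genes if g != moved]
        reordered.insert(25, moved)  # >2k away from origin
        g1 = Genome("A", tuple(genes))
        g2 = Genome("B", tuple(reordered))
        assert synteny_index(moved, g1, g2, k) == 0
        for gene in genes:
            p1 = g1.positions[gene]
            near_origin = min(abs(p1 - 5), 40 - abs(p1 - 5)) <= k
            near_target = min(abs(p1 - 25), 40 - abs(p1 - 25)) <= k + 1
            if not (near_origin or near_target or gene == moved):
                assert synteny_index(gene, g1, g2, k) == 2 * k


class TestInferRecipient:
    def _profiles(self, low_pairs, orgs=("A", "B", "C")):
        # gene 'x' has SI 0 in low pairs, 20 elsewhere; 99 background genes
        profiles = []
        pairs = [(a, b) for i, a in enumerate(orgs) for b in orgs[i + 1:]]
        for pair in pairs:
            si = {f"g{i}": 20 for i in range(99)}
            si["x"] = 0 if set(pair) in [set(p) for p in low_pairs] else 20
            profiles.append(SIProfile(pair, 10, si, frozenset(si)))
        return profiles

    def test_two_low_pairs_with_unique_intersection(self):
        profs = self._profiles([("A", "B"), ("A", "C")])
        assert infer_recipient("x", profs, 0.05) == "A"

    def test_single_low_pair_is_undetermined(self):
        profs = self._profiles([("A", "B")])
        assert infer_recipient("x", profs, 0.05) is None

    def test_all_pairs_low_is_undetermined(self):
        profs = self._profiles([("A", "B"), ("A", "C"), ("B", "C")])
        assert infer_recipient("x", profs, 0.05) is None
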