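from __future__ import annotations

import pytest

from cliquesig.ccp import (
    clique_connectivity_score,
    divergence_points,
    extend_profile,
    select_seed,
)
from cliquesig.cliques import Clique
from cliquesig.synthetic_data import generate_ccp_fixture


def C(genes, strength=1.0):
    return Clique(genes=tuple(sorted(genes)), strength=strength)


class TestSelectSeed:
    def test_unique_candidate(self):
        a = C("abcdefg", 2.0)
        sets = {"p1": [a], "p2": [C("abcdefg", 3.0)]}
        assert select_seed(sets, size=7).gene_set == a.gene_set

    def test_argmax_of_summed_strengths(self):
        sets = {
            "p1": [C("abcdefg", 5.0), C("hijklmn", 4.0)],
            "p2": [C("abcdefg", 5.0), C("hijklmn", 4.0)],
        }
        assert select_seed(sets, size=7).genes == tuple("abcdefg")
        assert select_seed(sets, size=7).strength == pytest.approx(10.0)

    def test_no_common_clique_rejected(self):
        sets = {"p1": [C("abcdefg")], "p2": [C("hijklmn")]}
        with pytest.raises(ValueError, match="common"):
            select_seed(sets, size=7)


class TestConnectivityScore:
    def test_mean_of_two(self):
        assert clique_connectivity_score(C("abc", 5.0), C("cde", 3.0)) == 4.0

    def test_equal_strengths(self):
        assert clique_connectivity_score(C("abc", 2.5), C("cde", 2.5)) == 2.5

    def test_symmetric(self):
        a, b = C("abc", 1.0), C("cde", 9.0)
        assert clique_connectivity_score(a, b) == clique_connectivity_score(b, a)


class TestExtendProfile:
    def test_chain_of_overlapping_seven_cliques(self):
        a = C("abcdefg", 3.0)
        b = C("bcdefgh", 2.0)  # nn(a,b)=6
        c = C("cdefghi", 1.0)  # nn(b,c)=6, nn(a,c)=5
        prof = extend_profile([a, b, c], a, mode="max")
        assert [x.genes for x in prof.chain] == [a.genes, b.genes, c.genes]
        assert prof.link_overlaps == [6, 6]
        assert prof.link_scores == [2.5, 1.5]

    def test_isolated_seed_terminates_immediately(self):
        prof = extend_profile([C("abcdefg"), C("hijklmn")], C("abcdefg"), mode="max")
        assert len(prof.chain) == 1

    def test_strength_breaks_overlap_ties(self):
        seed = C("abcdefg", 1.0)
        weak = C("defghij", 4.0)
        strong = C("defghik", 6.0)  # same nn=4 as weak
        prof = extend_profile([seed, weak, strong], seed, mode="max")
        assert prof.chain[1].genes == strong.genes

    def test_min_mode_prefers_smallest_overlap_and_respects_cap(self):
        seed = C("abcdefg", 1.0)
        near = C("cdefghi", 9.0)  # nn=5 > cap
        far = C("ghijklm", 2.0)  # nn=1
        prof = extend_profile([seed, near, far], seed, mode="min", nn_cap=4)
        # near (nn=5) is over the cap at the first step; from far it re-enters
        # with nn=3, within the cap
        assert [x.genes for x in prof.chain] == [seed.genes, far.genes, near.genes]
        assert prof.link_overlaps == [1, 3]

    def test_deterministic(self):
        cliques = [C("abcdefg", 1.0), C("defghij", 2.0), C("ghijklm", 3.0)]
        runs = [extend_profile(cliques, cliques[0], mode="max") for _ in range(3)]
        chains = [[x.genes for x in r.chain] for r in runs]
        assert chains[0] == chains[1] == chains[2]

    def test_seed_absent_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            extend_profile([C("abcdefg")], C("hijklmn"))

    def test_every_overlap_at_least_one_and_no_repeats(self):
        fixture = generate_ccp_fixture(chain_length=6, overlap=3, diverge_at=6, seed=3)
        for pop, cliques in fixture.clique_sets.items():
            seed = select_seed(fixture.clique_sets, size=7)
            for mode in ("max", "min"):
                prof = extend_profile(cliques, seed, mode=mode, population=pop)
                assert all(nn >= 1 for nn in prof.link_overlaps)
                gene_sets = [c.gene_set for c in prof.chain]
                assert len(set(gene_sets)) == len(gene_sets)
                assert len(prof.chain) <= len(cliques)


class TestDivergence:
    def test_identical_chains_no_divergence(self):
        p1 = extend_profile([C("abcdefg")], C("abcdefg"), population="p1")
        p2 = extend_profile([C("abcdefg")], C("abcdefg"), population="p2")
        assert divergence_points([p1, p2]) == {("p1", "p2"): None}

    def test_first_mismatch_position(self):
        seed = C("abcdefg", 5.0)
        b = C("defghij", 4.0)
        c1, c2 = C("hijklmn", 3.0), C("hijklmo", 3.0)
        p1 = extend_profile([seed, b, c1], seed, population="p1")
        p2 = extend_profile([seed, b, c2], seed, population="p2")
        assert divergence_points([p1, p2]) == {("p1", "p2"): 2}

    def test_divergence_at_seed_successor(self):
        seed = C("abcdefg", 5.0)
        p1 = extend_profile([seed, C("defghij", 4.0)], seed, population="p1")
        p2 = extend_profile([seed, C("defgxyz", 4.0)], seed, population="p2")
        assert divergence_points([p1, p2]) == {("p1", "p2"): 1}

    def test_prefix_chain_diverges_where_shorter_ends(self):
        seed = C("abcdefg", 5.0)
        b = C("defghij", 4.0)
        p1 = extend_profile([seed, b], seed, population="p1")
        p2 = extend_profile([seed], seed, population="p2")
        assert divergence_points([p1, p2]) == {("p1", "p2"): 1}

    def test_different_seeds_rejected(self):
        p1 = extend_profile([C("abcdefg")], C("abcdefg"), population="p1")
        p2 = extend_profile([C("hijklmn")], C("hijklmn"), population="p2")
        with pytest.raises(ValueError, match="seed"):
            divergence_points([p1, p2])


class TestPlantedFixtures:
    @pytest.mark.parametrize("diverge_at", [0, 1, 2])
    def test_walk_recovers_planted_chain_and_divergence(self, diverge_at):
        fixture = generate_ccp_fixture(
            chain_length=5, overlap=3, diverge_at=diverge_at, n_populations=3, seed=9
        )
        truth = fixture.ground_truth
        seed_clique = select_seed(fixture.clique_sets, size=7)
        assert sorted(seed_clique.genes) == sorted(truth["seed_clique"])
        profiles = []
        for pop, cliques in sorted(fixture.clique_sets.items()):
            prof = extend_profile(cliques, seed_clique, mode="max", population=pop)
            assert [list(c.genes) for c in prof.chain] == truth["chains"][pop]
            profiles.append(prof)
        for idx in divergence_points(profiles).values():
            assert idx == truth["divergence_index"]

    def test_min_mode_follows_chain_within_cap(self):
        fixture = generate_ccp_fixture(
            chain_length=4, overlap=3, diverge_at=4, n_populations=2, seed=5
        )
        seed_clique = select_seed(fixture.clique_sets, size=7)
        for pop, cliques in fixture.clique_sets.items():
            prof = extend_profile(cliques, seed_clique, mode="min", nn_cap=4, population=pop)
            assert [list(c.genes) for c in prof.chain] == fixture.ground_truth["chains"][pop]
            assert all(nn <= 4 for nn in prof.link_overlaps)

    def test_chain_length_one_is_just_the_seed(self):
        fixture = generate_ccp_fixture(chain_length=1, diverge_at=0, seed=1)
        seed_clique = select_seed(fixture.clique_sets, size=7)
        for cliques in fixture.clique_sets.values():
            prof = extend_profile(cliques, seed_clique, mode="max")
            assert len(prof.chain) == 1
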