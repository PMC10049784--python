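"""Pedigree validation, kinship, contribution and path enumeration."""

import itertools

import pytest

from haplodrop import (
    GenealogyError,
    Sex,
    build_genealogy,
    kinship_path_formula,
    prune_to_relevant,
    read_pedigree,
    write_pedigree,
)
from haplodrop.fixtures import PedigreeSpec, generate_pedigree

TRIO = [(3, 1, 2, 1), (1, 0, 0, 1), (2, 0, 0, 2)]


class TestBuild:
    def test_trio_structure(self):
        g = build_genealogy(TRIO)
        assert g.founders == {1, 2}
        assert g.probands == {3}
        order = {i: k for k, i in enumerate(g.topo_order)}
        assert order[1] < order[3] and order[2] < order[3]

    def test_single_founder_is_own_proband(self):
        g = build_genealogy([(1, 0, 0, 2)])
        assert g.founders == {1} == g.probands

    @pytest.mark.parametrize(
        "rows,fragment",
        [
            ([(3, 1, 2, 1), (1, 0, 0, 1)], "absent"),  # dangling mother
            ([(1, 0, 0, 1), (1, 0, 0, 1)], "duplicate"),
            ([(1, 0, 0, 1), (2, 0, 0, 1), (3, 1, 2, 1)], "wrong sex"),
            ([(1, 2, 0, 1), (2, 0, 0, 1)], "exactly one known parent"),
            ([], "empty"),
            ([(1, 0, 0, 1), (2, 0, 0, 2), (3, 1, 2, 9)], "sex"),
        ],
    )
    def test_invalid_pedigrees_rejected(self, rows, fragment):
        with pytest.raises(GenealogyError, match=fragment):
            build_genealogy(rows)

    def test_cycle_detected(self):
        # 3 and 4 are each other's ancestors through 5
        rows = [(2, 0, 0, 2), (3, 5, 2, 1), (4, 3, 2, 2), (5, 3, 4, 1)]
        with pytest.raises(GenealogyError, match="cycle"):
            build_genealogy(rows)

    def test_explicit_probands_override(self):
        g = build_genealogy(TRIO, probands=[1, 3])
        assert g.probands == {1, 3}

    def test_roundtrip_file(self, tmp_path):
        g = build_genealogy(TRIO)
        path = tmp_path / "ped.tsv"
        write_pedigree(g, path)
        g2 = read_pedigree(path)
        assert g2.individuals == g.individuals

    def test_read_comma_separated_no_header(self, tmp_path):
        path = tmp_path / "ped.csv"
        path.write_text("1,0,0,M\n2,0,0,F\n3,1,2,M\n")
        g = read_pedigree(path)
        assert g.individuals[3].sex is Sex.MALE
        assert g.founders == {1, 2}


class TestKinship:
    def test_distinct_founders_unrelated(self, pedigrees):
        g = pedigrees["trio"]
        assert g.kinship(1, 2) == 0.0

    def test_founder_self_kinship(self, pedigrees):
        assert pedigrees["trio"].kinship(1, 1) == 0.5

    @pytest.mark.parametrize(
        "name,pair,expected",
        [
            ("trio", (1, 3), 0.25),       # parent-offspring
            ("sib_quartet", (3, 4), 0.25),
            ("half_sibs", (4, 5), 0.125),
            ("cousin_loop", (7, 8), 0.0625),
            ("chain", (4, 7), 0.125),     # grandparent
            ("chain", (1, 7), 0.0625),    # great-grandparent
        ],
    )
    def test_known_coefficients(self, pedigrees, name, pair, expected):
        assert pedigrees[name].kinship(*pair) == pytest.approx(expected)

    def test_inbred_child_self_kinship(self, pedigrees):
        g = pedigrees["cousin_loop"]
        assert g.inbreeding(9) == pytest.approx(0.0625)
        assert g.kinship(9, 9) == pytest.approx(0.5 * (1 + 0.0625))

    def test_symmetry_and_path_formula_agree_everywhere(self, pedigrees):
        """The recursion and Wright's path-counting formula are independent
        derivations; they must agree on every pair of every fixture."""
        for g in pedigrees.values():
            ids = sorted(g.individuals)
            for a, b in itertools.combinations(ids, 2):
                phi = g.kinship(a, b)
                assert phi == pytest.approx(g.kinship(b, a))
                assert phi == pytest.approx(kinship_path_formula(g, a, b), abs=1e-12)

    def test_path_formula_on_random_consanguineous_pedigree(self):
        g = generate_pedigree(PedigreeSpec(4, 4, offspring_mean=2.0,
                                           consanguinity_rate=0.5, seed=42))
        ids = sorted(g.individuals)[-8:]
        for a, b in itertools.combinations(ids, 2):
            assert g.kinship(a, b) == pytest.approx(kinship_path_formula(g, a, b), abs=1e-12)


class TestContributionAndPaths:
    def test_parent_and_grandparent(self, pedigrees):
        g = pedigrees["chain"]
        assert g.genetic_contribution(3, 1) == 0.5
        assert g.genetic_contribution(7, 4) == 0.25

    def test_loop_two_paths_sum(self, pedigrees):
        g = pedigrees["cousin_loop"]
        assert g.enumerate_paths(1, 9) == [(1, 3, 7, 9), (1, 4, 8, 9)]
        assert g.genetic_contribution(9, 1) == pytest.approx(2 * 0.5 ** 3)

    def test_contributions_sum_to_one(self, pedigrees):
        for g in pedigrees.values():
            for p in g.probands:
                total = sum(g.genetic_contribution(p, f) for f in g.founders)
                assert total == pytest.approx(1.0)

    def test_no_path_between_unrelated(self, pedigrees):
        g = pedigrees["half_sibs"]
        assert g.enumerate_paths(2, 5) == []

    def test_chain_single_three_meiosis_path(self, pedigrees):
        paths = pedigrees["chain"].enumerate_paths(1, 7)
        assert len(paths) == 1 and len(paths[0]) - 1 == 3

    def test_non_founder_rejected(self, pedigrees):
        with pytest.raises(GenealogyError, match="not a founder"):
            pedigrees["trio"].genetic_contribution(3, 3)


class TestPrune:
    def test_trio_identity(self, pedigrees):
        pruned = pedigrees["trio"].prune_to_relevant([3])
        assert set(pruned.individuals) == {1, 2, 3}

    def test_unrelated_founder_removed(self):
        g = build_genealogy(TRIO + [(9, 0, 0, 2)])
        pruned, tracked = prune_to_relevant(g, [3], [1, 9])
        assert 9 not in pruned
        assert tracked == {1}

    def test_matches_bruteforce_descendant_sets(self):
        g = generate_pedigree(PedigreeSpec(4, 5, offspring_mean=2.5, seed=9))
        probands = sorted(g.probands)[:4]
        pruned = g.prune_to_relevant(probands)
        # brute force: keep anyone whose DFS descendant set meets the probands
        expected = set()
        for i in g.individuals:
            reach = {i}
            stack = [i]
            while stack:
                for c in g.children[stack.pop()]:
                    if c not in reach:
                        reach.add(c)
                        stack.append(c)
            if reach & set(probands):
                expected.add(i)
        assert set(pruned.individuals) == expected

    def test_prune_preserves_kinship(self, pedigrees):
        g = pedigrees["loop_concat"]
        pruned = g.prune_to_relevant([9])
        for a in pruned.individuals:
            for b in pruned.individuals:
                assert pruned.kinship(a, b) == pytest.approx(g.kinship(a, b))

    def test_empty_probands_rejected(self, pedigrees):
        with pytest.raises(GenealogyError, match="empty"):
            pedigrees["trio"].prune_to_relevant([])
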