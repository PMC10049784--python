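"""Traceback, pairwise IBD, and genotype conversion."""

import numpy as np
import pandas as pd
import pytest

from haplodrop import (
    GenealogyError,
    Haplotype,
    MeiosisModel,
    Replicate,
    SimulationConfig,
    compare_ibd,
    convert_genotypes,
    generate_founder_genotypes,
    simulate,
    traceback,
)

BP = 100_000_000


def cfg_for(probands, tracked=None, n_sim=100, L=1.0, seed=5, **kw):
    return SimulationConfig(
        probands=tuple(probands),
        tracked_founders=tuple(tracked) if tracked is not None else None,
        n_sim=n_sim, model=MeiosisModel("poisson", L, L), bp_len=BP, seed=seed, **kw,
    )


class TestTraceback:
    def test_trio_single_path_never_concatenated(self, pedigrees):
        g = pedigrees["trio"]
        reps = simulate(g, cfg_for([3], tracked=[1], n_sim=100, emit_all_nodes=True))
        for segs in traceback(reps, g, 3, 1):
            assert segs  # founder 1 is a parent: material always inherited
            for s in segs:
                assert s.paths == (s.paths[0],)
                assert s.paths[0].ids == (1, 3)
                assert not s.concatenated

    def test_chain_paths_subset_of_enumeration(self, pedigrees):
        g = pedigrees["chain"]
        allowed = set(g.enumerate_paths(1, 7))
        reps = simulate(g, cfg_for([7], tracked=[1], n_sim=300, emit_all_nodes=True))
        for segs in traceback(reps, g, 7, 1):
            for s in segs:
                assert all(p.ids in allowed for p in s.paths)
                assert not s.concatenated  # no loop: single route only

    def test_loop_paths_valid_and_concatenations_only_in_loops(self, pedigrees):
        g = pedigrees["loop_concat"]
        allowed = set(g.enumerate_paths(1, 11))
        reps = simulate(g, cfg_for([11], tracked=[1], n_sim=2000, L=2.5,
                                   emit_all_nodes=True, seed=7))
        n_cat = 0
        for segs in traceback(reps, g, 11, 1):
            for s in segs:
                assert all(p.ids in allowed for p in s.paths)
                if s.concatenated:
                    assert len(s.paths) >= 2
                    n_cat += 1
        assert n_cat > 0  # the loop admits multi-path segments

    def test_traced_segments_cover_all_founder_material(self, pedigrees):
        g = pedigrees["cousin_loop"]
        reps = list(simulate(g, cfg_for([9], tracked=[1], n_sim=50, emit_all_nodes=True)))
        traced = traceback(reps, g, 9, 1)
        for rep, segs in zip(reps, traced):
            expect = sum(
                hap.founder_fraction(1) for hap in rep.haplotypes[9]
            ) * BP
            assert sum(s.length for s in segs) == pytest.approx(expect)

    def test_requires_all_node_records(self, pedigrees):
        g = pedigrees["chain"]
        reps = simulate(g, cfg_for([7], tracked=[1], n_sim=30, seed=41))
        with pytest.raises(GenealogyError, match="all-node"):
            traceback(reps, g, 7, 1)

    def test_non_founder_rejected(self, pedigrees):
        g = pedigrees["trio"]
        with pytest.raises(GenealogyError, match="founder"):
            traceback([], g, 3, 3)


class TestCompareIBD:
    def test_parent_offspring_exact_quarter_every_replicate(self, pedigrees):
        g = pedigrees["trio"]
        res = compare_ibd(simulate(g, cfg_for([1, 3], n_sim=100)), 1, 3)
        assert np.all(res.mean_pairwise == 0.25)
        assert not res.lower_bound

    def test_union_at_least_mean_pairwise(self, pedigrees):
        g = pedigrees["sib_quartet"]
        res = compare_ibd(simulate(g, cfg_for([3, 4], n_sim=200)), 3, 4)
        assert np.all(res.union >= res.mean_pairwise)
        assert np.all((0 <= res.union) & (res.union <= 1))

    @pytest.mark.parametrize("name,pair", [
        ("sib_quartet", (3, 4)),
        ("half_sibs", (4, 5)),
        ("cousin_loop", (7, 8)),
    ])
    def test_expectation_is_kinship(self, pedigrees, name, pair):
        g = pedigrees[name]
        n = 2500
        res = compare_ibd(simulate(g, cfg_for(pair, n_sim=n, L=2.0, seed=13)), *pair)
        se = res.sd / np.sqrt(n)
        assert abs(res.mean - g.kinship(*pair)) < 3 * se

    def test_partial_tracking_flags_lower_bound(self, pedigrees):
        g = pedigrees["sib_quartet"]
        res = compare_ibd(simulate(g, cfg_for([3, 4], tracked=[1], n_sim=20)), 3, 4)
        assert res.lower_bound

    def test_unknown_individual_rejected(self, pedigrees):
        g = pedigrees["trio"]
        with pytest.raises(GenealogyError):
            compare_ibd(simulate(g, cfg_for([3], n_sim=2)), 3, 99)


def _unique_allele_table(bp_positions):
    labels = ["1.1", "1.2", "2.1", "2.2"]
    return pd.DataFrame({
        "bp": np.asarray(bp_positions, dtype=np.int64),
        **{lab: [f"{lab}@{p}" for p in bp_positions] for lab in labels},
    })


class TestConvertGenotypes:
    def test_no_recombination_reproduces_founder_columns(self, pedigrees):
        g = pedigrees["trio"]
        table = _unique_allele_table([10, BP // 2, BP - 10])
        reps = list(simulate(g, cfg_for([3], n_sim=10, L=0.0)))
        df = convert_genotypes(reps, table, probands=[3])
        for (sim, _), sub in df.groupby(["sim", "proband"]):
            pat, mat = reps[sim - 1].haplotypes[3]
            assert list(sub.allele_pat) == list(table[pat.labels[0]])
            assert list(sub.allele_mat) == list(table[mat.labels[0]])

    def test_alleles_switch_at_injected_breakpoint(self):
        positions = [100, 300, 500, 700, 900]
        table = _unique_allele_table(positions)
        hap = Haplotype((0, 600), ("1.1", "2.2"), 1000)
        other = Haplotype((0,), ("1.2",), 1000)
        rep = Replicate(1, {42: (hap, other)})
        df = convert_genotypes([rep], table)
        expect = [table["1.1"][i] if p < 600 else table["2.2"][i]
                  for i, p in enumerate(positions)]
        assert list(df.allele_pat) == expect

    def test_untracked_material_emits_missing_code(self):
        table = _unique_allele_table([50, 150])
        hap = Haplotype((0, 100), ("0", "1.1"), 200)
        rep = Replicate(1, {7: (hap, hap)})
        df = convert_genotypes([rep], table)
        assert list(df.allele_pat) == ["0", table["1.1"][1]]

    def test_marker_outside_range_rejected(self):
        table = _unique_allele_table([5000])
        rep = Replicate(1, {7: (Haplotype((0,), ("1.1",), 100),) * 2})
        with pytest.raises(ValueError, match="outside"):
            convert_genotypes([rep], table)

    def test_missing_label_column_rejected(self):
        table = _unique_allele_table([50]).drop(columns=["2.2"])
        rep = Replicate(1, {7: (Haplotype((0,), ("2.2",), 100),) * 2})
        with pytest.raises(ValueError, match="missing"):
            convert_genotypes([rep], table)

    def test_generated_table_round_trips(self, pedigrees, tmp_path):
        from haplodrop import read_founder_genotypes, write_founder_genotypes
        g = pedigrees["sib_quartet"]
        table = generate_founder_genotypes(g, markers=25, bp_len=BP, seed=3)
        assert list(table.columns) == ["bp", "1.1", "1.2", "2.1", "2.2"]
        assert (table.drop(columns="bp").nunique(axis=1) == 4).all()
        path = tmp_path / "geno.tsv"
        write_founder_genotypes(table, path)
        back = read_founder_genotypes(path)
        pd.testing.assert_frame_equal(back, table)
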