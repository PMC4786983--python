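"""Hypergeometric overlap tests, reciprocal best hits, leading edges."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toxmod.conservation import (
    chemical_class_enrichment,
    conserved_across_three,
    gene_list_overlap,
    hypergeom_p,
    leading_edge_union,
    reciprocal_best_hits,
)
from toxmod.gsea import EnrichmentResult
from toxmod.isa import Bicluster, ModuleSet


def brute_hypergeom_tail(k, K_a, K_b, N):
    """Independent oracle: exact pmf summation with integer binomials."""
    denom = math.comb(N, K_b)
    total = 0
    for x in range(k, min(K_a, K_b) + 1):
        if N - K_a >= K_b - x:
            total += math.comb(K_a, x) * math.comb(N - K_a, K_b - x)
    return total / denom


class TestHypergeomP:
    def test_zero_overlap_is_one(self):
        assert hypergeom_p(0, 5, 4, 10) == 1.0

    def test_analytic_case_1_over_42(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210 = 1/42
        assert hypergeom_p(4, 5, 4, 10) == pytest.approx(1 / 42, abs=1e-12)

    def test_forced_full_overlap_is_one(self):
        assert hypergeom_p(6, 6, 6, 6) == 1.0

    def test_matches_brute_force_small_universes(self):
        for N in range(1, 13):
            for K_a in range(N + 1):
                for K_b in range(N + 1):
                    for k in range(min(K_a, K_b) + 1):
                        assert hypergeom_p(k, K_a, K_b, N) == pytest.approx(
                            brute_hypergeom_tail(k, K_a, K_b, N), abs=1e-12
                        )

    @settings(deadline=None, max_examples=100)
    @given(st.data())
    def test_monotone_in_overlap(self, data):
        N = data.draw(st.integers(2, 60))
        K_a = data.draw(st.integers(1, N))
        K_b = data.draw(st.integers(1, N))
        ps = [hypergeom_p(k, K_a, K_b, N) for k in range(min(K_a, K_b) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            hypergeom_p(3, 2, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_p(1, 11, 5, 10)


def module(mid, pathways, chems=("c1",), universe=400):
    n = len(pathways)
    return Bicluster(
        row_scores=np.ones(n),
        col_scores=np.ones(len(chems)),
        row_ids=list(pathways),
        col_ids=list(chems),
        thr_row=1.5,
        thr_col=1.5,
        seed_index=0,
        n_iterations=1,
        robustness=1.0,
        module_id=mid,
    )


def module_set(mods):
    return ModuleSet(modules=mods)


PW = [f"PW{i:03d}" for i in range(400)]


class TestReciprocalBestHits:
    def test_identical_sets_self_match(self):
        mods = [module(f"mod{i}", PW[i * 10 : i * 10 + 10]) for i in range(4)]
        a, b = module_set(mods), module_set([module(m.module_id, m.row_ids) for m in mods])
        matches = reciprocal_best_hits(a, b, N=400, alpha=0.001)
        assert {(m.module_a, m.module_b) for m in matches} == {
            (f"mod{i}", f"mod{i}") for i in range(4)
        }
        assert all(m.p < 0.001 and m.reciprocal for m in matches)

    def test_zero_overlap_unmatched(self):
        a = module_set([module("a1", PW[:10])])
        b = module_set([module("b1", PW[100:110])])
        assert reciprocal_best_hits(a, b, N=400) == []

    def test_empty_module_set_gives_empty_list(self):
        a = module_set([module("a1", PW[:10])])
        assert reciprocal_best_hits(a, module_set([]), N=400) == []
        assert reciprocal_best_hits(module_set([]), a, N=400) == []

    def test_non_reciprocal_pair_not_reported(self):
        # a1's best is b1, but b1 prefers a2 (larger overlap) -> no a1-b1 match
        a1 = module("a1", PW[0:12])
        a2 = module("a2", PW[0:20])
        b1 = module("b1", PW[0:20])
        matches = reciprocal_best_hits(module_set([a1, a2]), module_set([b1]), N=400)
        pairs = {(m.module_a, m.module_b) for m in matches}
        assert ("a1", "b1") not in pairs
        assert ("a2", "b1") in pairs

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(0)
        a = module_set(
            [module(f"a{i}", rng.choice(PW, 15, replace=False)) for i in range(5)]
        )
        b = module_set(
            [module(f"b{i}", rng.choice(PW, 15, replace=False)) for i in range(5)]
        )
        ab = {(m.module_a, m.module_b) for m in reciprocal_best_hits(a, b, N=400, alpha=0.5)}
        ba = {(m.module_b, m.module_a) for m in reciprocal_best_hits(b, a, N=400, alpha=0.5)}
        assert ab == ba


class TestConservedAcrossThree:
    def make_set(self, prefix, shared, private):
        mods = [module(f"{prefix}_s{i}", p) for i, p in enumerate(shared)]
        mods += [module(f"{prefix}_p{i}", p) for i, p in enumerate(private)]
        return module_set(mods)

    def test_identical_sets_all_form_triples(self):
        blocks = [PW[i * 20 : i * 20 + 20] for i in range(4)]
        rlv = self.make_set("rlv", blocks, [])
        prh = self.make_set("prh", blocks, [])
        phh = self.make_set("phh", blocks, [])
        triples = conserved_across_three(rlv, prh, phh, N=400, alpha=0.001)
        assert len(triples) == 4
        assert all(len(t.shared_pathways) == 20 for t in triples)

    def test_one_empty_set_gives_no_triples(self):
        blocks = [PW[:20]]
        rlv = self.make_set("rlv", blocks, [])
        prh = self.make_set("prh", blocks, [])
        assert conserved_across_three(rlv, prh, module_set([]), N=400) == []

    def test_only_shared_modules_form_triples(self):
        shared = [PW[i * 20 : i * 20 + 20] for i in range(5)]
        rlv = self.make_set("rlv", shared, [PW[100:115]])
        prh = self.make_set("prh", shared, [PW[150:165]])
        phh = self.make_set("phh", shared, [PW[200:215]])
        triples = conserved_across_three(rlv, prh, phh, N=400, alpha=0.001)
        assert {t.rlv_module for t in triples} == {f"rlv_s{i}" for i in range(5)}


class TestChemicalClassEnrichment:
    def test_disjoint_class_gives_p_one(self):
        m = module("m", PW[:10], chems=[f"c{i}" for i in range(10)])
        uni = [f"c{i}" for i in range(115)]
        k, p, sig = chemical_class_enrichment(m, [f"c{i}" for i in range(50, 75)][:25], uni)
        assert (k, p) == (0, 1.0) and not sig

    def test_fully_in_class_significant(self):
        m = module("m", PW[:10], chems=[f"c{i}" for i in range(10)])
        uni = [f"c{i}" for i in range(115)]
        cls = [f"c{i}" for i in range(25)]
        k, p, sig = chemical_class_enrichment(m, cls, uni)
        assert k == 10
        assert p == pytest.approx(brute_hypergeom_tail(10, 10, 25, 115), rel=1e-10)
        assert sig

    def test_class_equal_universe_forced(self):
        m = module("m", PW[:5], chems=["c1", "c2"])
        uni = ["c1", "c2", "c3"]
        k, p, sig = chemical_class_enrichment(m, uni, uni)
        assert p == 1.0

    def test_empty_universe_rejected(self):
        m = module("m", PW[:5], chems=[])
        with pytest.raises(ValueError, match="universe"):
            chemical_class_enrichment(m, [], [])


def eres(pathway, chem, leading):
    return EnrichmentResult(
        pathway_id=pathway,
        chemical_id=chem,
        es=0.5,
        nes=1.2,
        p_nominal=0.05,
        n_overlap=len(leading),
        leading_edge=frozenset(leading),
    )


class TestLeadingEdgeUnion:
    def test_single_cell(self):
        m = module("m", ["P1"], chems=["c1"])
        store = {("P1", "c1"): eres("P1", "c1", {"g1", "g2"})}
        assert leading_edge_union(m, store) == {"g1", "g2"}

    def test_union_over_pathways(self):
        m = module("m", ["P1", "P2"], chems=["c1"])
        store = {
            ("P1", "c1"): eres("P1", "c1", {"g1", "g2"}),
            ("P2", "c1"): eres("P2", "c1", {"g2", "g3"}),
        }
        assert leading_edge_union(m, store) == {"g1", "g2", "g3"}

    def test_missing_cell_listed(self):
        m = module("m", ["P1", "P2"], chems=["c1"])
        store = {("P1", "c1"): eres("P1", "c1", {"g1"})}
        with pytest.raises(ValueError, match="P2"):
            leading_edge_union(m, store)

    def test_empty_module_rejected(self):
        m = module("m", ["P1"], chems=[])
        with pytest.raises(ValueError, match="empty"):
            leading_edge_union(m, {})


class TestGeneListOverlap:
    def test_identical_lists(self):
        uni = [f"g{i}" for i in range(20)]
        k, p = gene_list_overlap(uni[:6], uni[:6], uni)
        assert k == 6
        assert p == pytest.approx(brute_hypergeom_tail(6, 6, 6, 20), rel=1e-10)

    def test_disjoint_lists_p_one(self):
        uni = [f"g{i}" for i in range(20)]
        k, p = gene_list_overlap(uni[:5], uni[10:15], uni)
        assert (k, p) == (0, 1.0)

    def test_example_against_brute_force(self):
        uni = [f"g{i}" for i in range(20)]
        a = uni[:6]
        b = uni[2:6] + uni[10:11]  # |b|=5, overlap 4
        k, p = gene_list_overlap(a, b, uni)
        assert k == 4
        assert p == pytest.approx(brute_hypergeom_tail(4, 6, 5, 20), abs=1e-12)

    def test_subset_precondition(self):
        with pytest.raises(ValueError, match="subset"):
            gene_list_overlap(["zz"], ["g1"], ["g1", "g2"])
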