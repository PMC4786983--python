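"""Preranked GSEA: enrichment score, permutation null, NES, matrices."""

import numpy as np
import pytest
from scipy import stats

from toxmod.association import RankedList
from toxmod.data_model import PathwayCollection
from toxmod.gsea import (
    build_enrichment_matrix,
    enrichment_score,
    normalize_and_p,
    null_distribution,
    run_gsea,
)
from tests.conftest import make_ranked


def brute_force_es(ranked: RankedList, members: set, weight: float = 1.0):
    """Independent oracle: explicit walk accumulating hit/miss increments."""
    n = len(ranked)
    hits = [g in members for g in ranked.gene_ids]
    n_hits = sum(hits)
    total = sum(abs(s) ** weight for s, h in zip(ranked.scores, hits) if h)
    running, cur = [], 0.0
    for i in range(n):
        if hits[i]:
            cur += (abs(ranked.scores[i]) ** weight) / total if total > 0 else 1.0 / n_hits
        else:
            cur -= 1.0 / (n - n_hits)
        running.append(cur)
    m = max(abs(v) for v in running)
    # near-ties between peak and trough resolve to the earlier position
    best = min(i for i in range(n) if abs(running[i]) >= m - 1e-9)
    return running[best], running


class TestEnrichmentScore:
    def test_worked_example(self, ranked10):
        es, running, leading = enrichment_score(ranked10, {"g2", "g5", "g9"})
        assert es == pytest.approx(0.4538, abs=5e-5)
        assert leading == {"g2", "g5"}
        assert np.argmax(running) == 4  # peak right after the hit at rank 5

    def test_single_top_hit_scores_one(self, ranked10):
        es, _, leading = enrichment_score(ranked10, {"g1"})
        assert es == 1.0
        assert leading == {"g1"}

    def test_disjoint_set_rejected(self, ranked10):
        with pytest.raises(ValueError, match="overlap"):
            enrichment_score(ranked10, {"nope"})

    def test_full_universe_rejected(self, ranked10):
        with pytest.raises(ValueError, match="whole"):
            enrichment_score(ranked10, set(ranked10.gene_ids))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(5, 51))
            ranked = make_ranked(n, rng)
            k = int(rng.integers(1, min(10, n - 1) + 1))
            members = set(rng.choice(ranked.gene_ids, size=k, replace=False))
            es, running, _ = enrichment_score(ranked, members)
            es_ref, running_ref = brute_force_es(ranked, members)
            assert abs(es - es_ref) < 1e-12
            assert np.allclose(running, running_ref, atol=1e-12)

    def test_running_sum_ends_at_zero(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            ranked = make_ranked(int(rng.integers(5, 40)), rng)
            k = int(rng.integers(1, len(ranked)))
            members = set(rng.choice(ranked.gene_ids, size=k, replace=False))
            _, running, _ = enrichment_score(ranked, members)
            assert abs(running[-1]) < 1e-12

    def test_es_bounded(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            ranked = make_ranked(int(rng.integers(5, 40)), rng)
            k = int(rng.integers(1, len(ranked)))
            members = set(rng.choice(ranked.gene_ids, size=k, replace=False))
            es, _, _ = enrichment_score(ranked, members)
            assert -1.0 <= es <= 1.0

    def test_reversal_negates_score(self):
        rng = np.random.default_rng(9)
        ranked = make_ranked(30, rng)
        members = set(rng.choice(ranked.gene_ids, size=6, replace=False))
        es, _, _ = enrichment_score(ranked, members)
        flipped = RankedList(ranked.gene_ids[::-1].copy(), -ranked.scores[::-1], "c")
        es_rev, _, _ = enrichment_score(flipped, members)
        assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_matches_gseapy_reference(self):
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(150)]
        scores = np.sort(rng.normal(size=150))[::-1]
        ranked = RankedList(np.array(genes, dtype=object), scores)
        sets = {f"S{j}": list(rng.choice(genes, size=20, replace=False)) for j in range(4)}
        ref = gseapy.prerank(
            rnk=pd.Series(scores, index=genes),
            gene_sets=sets,
            permutation_num=5,
            min_size=5,
            max_size=100,
            seed=1,
            outdir=None,
            no_plot=True,
        ).res2d.set_index("Term")["ES"]
        for name, members in sets.items():
            es, _, _ = enrichment_score(ranked, set(members))
            assert es == pytest.approx(float(ref.loc[name]), abs=1e-6)


class TestNullDistribution:
    def test_deterministic_under_seed(self, ranked10):
        x = null_distribution(ranked10, 3, 50, 123)
        y = null_distribution(ranked10, 3, 50, 123)
        assert np.array_equal(x, y)

    def test_symmetric_scores_give_symmetric_null(self):
        scores = np.concatenate([np.arange(50, 0, -1.0), -np.arange(1, 51.0)])
        genes = np.array([f"g{i}" for i in range(100)], dtype=object)
        ranked = RankedList(genes, scores)
        null = null_distribution(ranked, 10, 10_000, 5)
        ks = stats.ks_2samp(null, -null)
        assert ks.pvalue > 0.01

    def test_set_size_bounds_enforced(self, ranked10):
        with pytest.raises(ValueError):
            null_distribution(ranked10, 10, 10, 0)
        with pytest.raises(ValueError):
            null_distribution(ranked10, 0, 10, 0)

    def test_agrees_with_scalar_es(self, ranked10):
        # each null draw equals the scalar ES of the same random set
        rng = np.random.default_rng(3)
        null = null_distribution(ranked10, 3, 20, np.random.default_rng(3))
        keys = rng.random((20, 10))
        for i in range(20):
            pos = np.argpartition(keys[i], 2)[:3]
            members = {ranked10.gene_ids[j] for j in pos}
            es, _, _ = enrichment_score(ranked10, members)
            assert es == pytest.approx(null[i], abs=1e-12)


class TestNormalizeAndP:
    def test_nes_one_at_null_mean(self):
        null = np.array([0.2, 0.4, -0.3])
        nes, _ = normalize_and_p(0.3, null)
        assert nes == pytest.approx(1.0)

    def test_zero_es_convention(self):
        nes, p = normalize_and_p(0.0, np.array([0.1, -0.1]))
        assert (nes, p) == (0.0, 1.0)

    def test_extreme_es_smoothed_p(self):
        null = np.concatenate([np.linspace(0.01, 0.5, 999), [-0.2]])
        _, p = normalize_and_p(0.99, null)
        assert p == pytest.approx(1 / 1000)

    def test_no_same_sign_null_is_masked_not_raised(self):
        nes, p = normalize_and_p(0.5, np.array([-0.1, -0.2]))
        assert np.isnan(nes) and np.isnan(p)


class TestRunGsea:
    def test_top_block_pathway_positive(self, ranked10):
        coll = PathwayCollection(sets={"top": frozenset({"g1", "g2", "g3"})})
        res = run_gsea(ranked10, coll, n_perm=200, rng_seed=0, min_overlap=2)
        assert res[0].nes > 0 and not res[0].masked

    def test_small_overlap_masked(self, ranked10):
        coll = PathwayCollection(
            sets={"tiny": frozenset({"g1"}), "ok": frozenset({"g2", "g3", "g9"})}
        )
        res = run_gsea(ranked10, coll, n_perm=50, rng_seed=0, min_overlap=3)
        by_id = {r.pathway_id: r for r in res}
        assert by_id["tiny"].masked and not by_id["ok"].masked

    def test_deterministic_result_table(self, ranked10):
        coll = PathwayCollection(sets={"a": frozenset({"g2", "g4", "g7"})})
        r1 = run_gsea(ranked10, coll, n_perm=100, rng_seed=7, min_overlap=2)
        r2 = run_gsea(ranked10, coll, n_perm=100, rng_seed=7, min_overlap=2)
        assert r1 == r2

    def test_empty_collection_rejected(self, ranked10):
        with pytest.raises(ValueError, match="empty"):
            run_gsea(ranked10, PathwayCollection(sets={}), n_perm=10)


class TestBuildEnrichmentMatrix:
    def make_results(self, rng_seed=0, chems=("c1", "c2", "c3")):
        rng = np.random.default_rng(rng_seed)
        out = {}
        for chem in chems:
            ranked = make_ranked(40, rng)
            ranked.chemical_id = chem
            coll = PathwayCollection(
                sets={
                    "P1": frozenset(rng.choice(ranked.gene_ids, 8, replace=False)),
                    "P2": frozenset(rng.choice(ranked.gene_ids, 2, replace=False)),
                }
            )
            out[chem] = run_gsea(ranked, coll, n_perm=30, rng_seed=1, min_overlap=5)
        return out

    def test_shape_and_column_order(self):
        res = self.make_results()
        m = build_enrichment_matrix(res)
        assert m.nes.shape == (2, 3)
        assert m.chemical_ids == ["c1", "c2", "c3"]

    def test_masked_cells_are_zero_with_mask(self):
        m = build_enrichment_matrix(self.make_results())
        assert m.mask.loc["P2"].all()  # overlap 2 < min_overlap 5
        assert (m.nes.loc["P2"] == 0).all()

    def test_inconsistent_universe_rejected(self):
        res = self.make_results()
        res["c3"] = res["c3"][:1]
        with pytest.raises(ValueError, match="universe"):
            build_enrichment_matrix(res)
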