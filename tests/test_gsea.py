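"""Ranked-list enrichment: running-sum score against a naive oracle,
permutation p-values, and collection-level adjustment."""
import numpy as np
import pandas as pd
import pytest

import miraxis as mx
from miraxis.gsea import enrichment_score, gsea_collection, gsea_permutation, rank_genes
from miraxis.types import ValidationError


def naive_running_sum_es(scores, hit_mask, weight):
    """Independent step-by-step recomputation of the running-sum ES."""
    scores = np.asarray(scores, dtype=float)
    hit = np.asarray(hit_mask, dtype=bool)
    w = np.abs(scores) ** weight
    W = w[hit].sum()
    n_miss = (~hit).sum()
    s, best, best_abs = 0.0, 0.0, -1.0
    for i in range(scores.size):
        s += w[i] / W if hit[i] else -1.0 / n_miss
        if abs(s) > best_abs:
            best_abs, best = abs(s), s
    return best


def make_ranked(scores, ids=None):
    ids = ids if ids is not None else [f"g{i:03d}" for i in range(len(scores))]
    de = pd.DataFrame(dict(feature_id=ids, log2fc=scores, pvalue=[0.5] * len(scores)))
    return rank_genes(de)


class TestRankGenes:
    def test_orders_most_up_to_most_down(self):
        de = pd.DataFrame(dict(feature_id=["a", "b", "c"], log2fc=[0.0, 2.0, -1.0],
                               pvalue=[0.5] * 3))
        assert list(rank_genes(de)["gene_id"]) == ["b", "a", "c"]

    def test_ties_break_lexicographically(self):
        de = pd.DataFrame(dict(feature_id=["z", "a", "m"], log2fc=[1.0, 1.0, 1.0],
                               pvalue=[0.5] * 3))
        assert list(rank_genes(de)["gene_id"]) == ["a", "m", "z"]

    def test_signed_logp_sign_dominates(self):
        de = pd.DataFrame(dict(feature_id=["dn", "up"], log2fc=[-1.0, 0.1],
                               pvalue=[0.01, 0.5]))
        ranked = rank_genes(de, metric="signed_logp")
        assert list(ranked["gene_id"]) == ["up", "dn"]

    def test_missing_p_falls_back_to_lfc(self, caplog):
        de = pd.DataFrame(dict(feature_id=["a", "b"], log2fc=[1.0, 2.0],
                               pvalue=[np.nan, 0.5]))
        with caplog.at_level("WARNING"):
            ranked = rank_genes(de, metric="signed_logp")
        assert list(ranked["gene_id"]) == ["b", "a"]
        assert any("falling back" in r.message for r in caplog.records)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            rank_genes(pd.DataFrame(columns=["feature_id", "log2fc", "pvalue"]))


class TestEnrichmentScore:
    def test_perfect_top_concentration_unweighted(self):
        ranked = make_ranked([4.0, 3.0, 2.0, 1.0])
        res = enrichment_score(ranked, set(ranked["gene_id"][:2]), weight=0)
        assert res.es == pytest.approx(1.0)
        assert np.allclose(res.running_sum, [0.5, 1.0, 0.5, 0.0])
        assert res.leading_edge == list(ranked["gene_id"][:2])

    def test_perfect_bottom_concentration_unweighted(self):
        ranked = make_ranked([4.0, 3.0, 2.0, 1.0])
        res = enrichment_score(ranked, set(ranked["gene_id"][2:]), weight=0)
        assert res.es == pytest.approx(-1.0)

    def test_weighted_small_case_matches_naive_oracle(self):
        ranked = make_ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        gene_set = {ranked["gene_id"][0], ranked["gene_id"][3]}
        res = enrichment_score(ranked, gene_set, weight=1)
        hit = ranked["gene_id"].isin(gene_set).to_numpy()
        assert res.es == pytest.approx(
            naive_running_sum_es(ranked["score"], hit, 1), abs=1e-12
        )

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_random_instances_match_naive_oracle(self, weight):
        rng = np.random.default_rng(17)
        for _ in range(100):
            N = int(rng.integers(5, 51))
            k = int(rng.integers(1, N))
            ranked = make_ranked(np.sort(rng.normal(0, 1, N))[::-1])
            members = set(rng.choice(ranked["gene_id"], k, replace=False))
            res = enrichment_score(ranked, members, weight=weight)
            hit = ranked["gene_id"].isin(members).to_numpy()
            assert res.es == pytest.approx(
                naive_running_sum_es(ranked["score"], hit, weight), abs=1e-12
            )

    def test_reversed_ranking_negates_unweighted_es(self):
        rng = np.random.default_rng(23)
        scores = np.sort(rng.normal(0, 1, 30))[::-1]
        ranked = make_ranked(scores)
        members = set(rng.choice(ranked["gene_id"], 7, replace=False))
        fwd = enrichment_score(ranked, members, weight=0).es
        # reversing the ranking = negating the metric: same genes, flipped order
        rev = pd.DataFrame(
            dict(gene_id=ranked["gene_id"][::-1].to_numpy(),
                 score=-ranked["score"][::-1].to_numpy())
        )
        bwd = enrichment_score(rev, members, weight=0).es
        assert bwd == pytest.approx(-fwd, abs=1e-9)

    def test_reversed_ranking_flips_weighted_sign(self):
        rng = np.random.default_rng(29)
        scores = np.sort(rng.normal(0, 1, 40))[::-1]
        ranked = make_ranked(scores)
        members = set(ranked["gene_id"][:8])
        fwd = enrichment_score(ranked, members, weight=1).es
        rev = pd.DataFrame(
            dict(gene_id=ranked["gene_id"][::-1].to_numpy(),
                 score=-ranked["score"][::-1].to_numpy())
        )
        bwd = enrichment_score(rev, members, weight=1).es
        assert np.sign(bwd) == -np.sign(fwd)

    def test_no_overlap_rejected(self):
        ranked = make_ranked([1.0, 2.0])
        with pytest.raises(ValidationError):
            enrichment_score(ranked, {"absent"})

    def test_dropped_members_counted(self):
        ranked = make_ranked([3.0, 2.0, 1.0])
        res = enrichment_score(ranked, {ranked["gene_id"][0], "absent"}, weight=0)
        assert res.n_dropped == 1 and res.n_hits == 1


class TestPermutationTest:
    def test_perfect_top_set_is_unbeatable(self):
        rng = np.random.default_rng(31)
        ranked = make_ranked(np.sort(rng.normal(0, 1, 1000))[::-1])
        top = set(ranked["gene_id"][:25])
        res = gsea_permutation(ranked, top, n_perm=1000, weight=1, seed=1)
        # no permutation ties or beats a perfectly concentrated set, so the
        # numerator of the sign-conditioned p is exactly 1
        n_same = round(1 / res.pvalue) - 1
        assert res.pvalue == pytest.approx(1 / (1 + n_same))
        assert res.pvalue < 0.01
        assert res.es > 0.9

    def test_same_seed_reproduces_result(self):
        rng = np.random.default_rng(37)
        ranked = make_ranked(rng.normal(0, 1, 300))
        members = set(rng.choice(ranked["gene_id"], 20, replace=False))
        r1 = gsea_permutation(ranked, members, n_perm=200, seed=5)
        r2 = gsea_permutation(ranked, members, n_perm=200, seed=5)
        assert (r1.es, r1.nes, r1.pvalue) == (r2.es, r2.nes, r2.pvalue)

    def test_too_few_permutations_rejected(self):
        ranked = make_ranked([1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            gsea_permutation(ranked, {ranked["gene_id"][0]}, n_perm=10, seed=1)


class TestCollection:
    def test_single_set_padj_equals_p(self):
        rng = np.random.default_rng(41)
        ranked = make_ranked(rng.normal(0, 1, 200))
        coll = {"only": set(rng.choice(ranked["gene_id"], 15, replace=False))}
        df, skipped = gsea_collection(ranked, coll, n_perm=200, seed=2)
        assert df.iloc[0]["padj"] == df.iloc[0]["pvalue"]
        assert skipped == []

    def test_no_overlap_sets_are_skipped(self):
        rng = np.random.default_rng(43)
        ranked = make_ranked(rng.normal(0, 1, 100))
        coll = {
            "real": set(rng.choice(ranked["gene_id"], 10, replace=False)),
            "ghost": {"x1", "x2"},
        }
        df, skipped = gsea_collection(ranked, coll, n_perm=200, seed=3)
        assert skipped == ["ghost"]
        assert list(df["set_id"]) == ["real"]

    def test_planted_shift_set_ranks_first(self):
        rng = np.random.default_rng(47)
        N = 800
        ids = [f"g{i:04d}" for i in range(N)]
        lfc = rng.normal(0, 1, N)
        planted = list(rng.choice(ids, 10, replace=False))
        lfc[np.isin(ids, planted)] += 2.5
        de = pd.DataFrame(dict(feature_id=ids, log2fc=lfc, pvalue=[0.5] * N))
        ranked = rank_genes(de)
        coll = {"planted": set(planted)}
        for i in range(20):
            coll[f"null{i:02d}"] = set(rng.choice(ids, 10, replace=False))
        df, _ = gsea_collection(ranked, coll, n_perm=500, seed=4)
        assert df.iloc[0]["set_id"] == "planted"
        assert df.iloc[0]["es"] > 0
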