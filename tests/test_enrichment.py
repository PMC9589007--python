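"""Competitive test, preranked GSEA, consensus, ORA, enrichment graph."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tissueprot.containers import GeneSetCollection
from tissueprot.enrichment import (
    build_enrichment_graph,
    camera_pr,
    consensus,
    gsea_es_bruteforce,
    gsea_preranked,
    hypergeom_ora,
)


def ranked_series(stats_arr):
    return pd.Series(
        np.asarray(stats_arr, dtype=float),
        index=[f"g{i}" for i in range(len(stats_arr))],
    )


class TestCamera:
    def test_equal_means_gives_p_one(self):
        # set {2, -2} has mean 0, rest {1, -1, 3, -3} has mean 0
        ranked = ranked_series([2, -2, 1, -1, 3, -3])
        sets = GeneSetCollection({"s": ["g0", "g1"]})
        res = camera_pr(ranked, sets, rho=0.0)
        assert res.loc["s", "t"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["s", "p"] == pytest.approx(1.0)

    def test_rho_zero_equals_pooled_t(self):
        rng = np.random.default_rng(50)
        ranked = ranked_series(rng.normal(size=200))
        members = [f"g{i}" for i in rng.choice(200, 30, replace=False)]
        sets = GeneSetCollection({"s": members})
        res = camera_pr(ranked, sets, rho=0.0)
        in_set = ranked.index.isin(members)
        oracle = stats.ttest_ind(ranked[in_set], ranked[~in_set], equal_var=True)
        assert abs(res.loc["s", "p"] - oracle.pvalue) < 1e-10

    def test_vif_deflates_statistic(self):
        rng = np.random.default_rng(51)
        ranked = ranked_series(rng.normal(size=300))
        members = [f"g{i}" for i in range(101)]
        sets = GeneSetCollection({"s": members})
        t0 = camera_pr(ranked, sets, rho=0.0).loc["s", "t"]
        t1 = camera_pr(ranked, sets, rho=0.01).loc["s", "t"]
        # VIF = 1 + 100 * 0.01 = 2 doubles the set's variance share
        G, m = 300, 101
        expected = t0 * np.sqrt((1 / m + 1 / (G - m)) / (2 / m + 1 / (G - m)))
        assert t1 == pytest.approx(expected, rel=1e-12)

    def test_direction_sign(self):
        ranked = ranked_series([5.0, 4.0, 0.0, -1.0, -2.0, -3.0])
        sets = GeneSetCollection({"up": ["g0", "g1"], "down": ["g4", "g5"]})
        res = camera_pr(ranked, sets, rho=0.0)
        assert res.loc["up", "direction"] == "up"
        assert res.loc["down", "direction"] == "down"


class TestGseaEs:
    def test_top_gene_scores_one(self):
        ranked = ranked_series([3.0, 2.0, 1.0, 0.5])
        sets = GeneSetCollection({"top": ["g0"]})
        res = gsea_preranked(ranked, sets, n_perm=10, min_size=1, seed=0)
        assert res.loc["top", "ES"] == pytest.approx(1.0)

    def test_whole_list_scores_one(self):
        ranked = ranked_series([3.0, 2.0, 1.0])
        es = gsea_es_bruteforce(ranked, ["g0", "g1", "g2"])
        assert es == pytest.approx(1.0)

    def test_exhaustive_oracle_agreement(self):
        # every subset of every list with G <= 10 genes
        rng = np.random.default_rng(52)
        for G in (4, 7, 10):
            ranked = ranked_series(np.sort(rng.normal(size=G))[::-1])
            genes = list(ranked.index)
            sets = {}
            for m in range(1, G):
                for k, members in enumerate(itertools.combinations(genes, m)):
                    sets[f"m{m}_{k}"] = list(members)
            coll = GeneSetCollection(sets)
            res = gsea_preranked(ranked, coll, n_perm=2, min_size=1,
                                 max_size=G - 1, seed=1)
            for name, members in coll.items():
                assert res.loc[name, "ES"] == pytest.approx(
                    gsea_es_bruteforce(ranked, members), abs=1e-12
                ), name

    def test_permutation_p_matches_exhaustive_null(self):
        rng = np.random.default_rng(53)
        G, m = 8, 3
        ranked = ranked_series(np.sort(rng.normal(size=G))[::-1])
        genes = list(ranked.index)
        target = genes[:3]
        res = gsea_preranked(
            ranked, GeneSetCollection({"s": target}),
            n_perm=40_000, min_size=1, max_size=G - 1, seed=2,
        )
        es_obs = res.loc["s", "ES"]
        null = np.array(
            [gsea_es_bruteforce(ranked, c)
             for c in itertools.combinations(genes, m)]
        )
        same = null >= 0 if es_obs >= 0 else null < 0
        p_exact = (np.abs(null[same]) >= abs(es_obs)).mean()
        assert res.loc["s", "p"] == pytest.approx(p_exact, abs=0.02)

    def test_planted_set_significant_across_seeds(self):
        rng = np.random.default_rng(54)
        stats_arr = rng.normal(size=500)
        stats_arr[:20] += 3.0
        ranked = ranked_series(stats_arr)
        members = [f"g{i}" for i in range(20)]
        coll = GeneSetCollection({"planted": members})
        ps = [
            gsea_preranked(ranked, coll, n_perm=10_000, seed=s).loc["planted", "p"]
            for s in (1, 2)
        ]
        assert all(p < 0.05 for p in ps)
        assert abs(ps[0] - ps[1]) < 0.01  # Monte-Carlo agreement

    def test_size_filter(self):
        ranked = ranked_series(np.arange(50, 0, -1))
        coll = GeneSetCollection({"small": ["g0", "g1"], "ok": [f"g{i}" for i in range(8)]})
        res = gsea_preranked(ranked, coll, n_perm=10, min_size=5, seed=0)
        assert list(res.index) == ["ok"]

    def test_leading_edge_for_positive_set(self):
        ranked = ranked_series([3.0, 2.0, 1.0, 0.5, 0.1, 0.05])
        coll = GeneSetCollection({"s": ["g0", "g1", "g5"]})
        res = gsea_preranked(ranked, coll, n_perm=10, min_size=1, seed=0)
        assert res.loc["s", "leading_edge"] == ["g0", "g1"]


class TestConsensus:
    @staticmethod
    def tables(camera_p, gsea_p, camera_dir, gsea_dir):
        idx = [f"s{i}" for i in range(len(camera_p))]
        cam = pd.DataFrame(
            {"size": 10, "p": camera_p, "direction": camera_dir}, index=idx
        )
        gs = pd.DataFrame(
            {
                "size": 10,
                "ES": [0.5] * len(idx),
                "NES": [1.5] * len(idx),
                "p": gsea_p,
                "direction": gsea_dir,
                "leading_edge": [[] for _ in idx],
            },
            index=idx,
        )
        return cam, gs

    def test_discordant_directions_blocked(self):
        cam, gs = self.tables([1e-6], [1e-6], ["up"], ["down"])
        out = consensus(cam, gs)
        assert not out["consensus"].any()
        assert out["direction"].iloc[0] == "discordant"

    def test_one_method_short_of_alpha(self):
        cam, gs = self.tables([0.04, 1.0], [0.06, 1.0], ["up", "up"], ["up", "up"])
        out = consensus(cam, gs, alpha=0.05)
        assert not out["consensus"].any()

    def test_consensus_subset_of_each_method(self):
        rng = np.random.default_rng(55)
        n = 40
        cam, gs = self.tables(
            rng.uniform(size=n), rng.uniform(size=n), ["up"] * n, ["up"] * n
        )
        out = consensus(cam, gs, alpha=0.5)
        assert (out.loc[out["consensus"], "camera_q"] < 0.5).all()
        assert (out.loc[out["consensus"], "gsea_q"] < 0.5).all()


class TestOra:
    def test_exact_small_case(self):
        background = [f"b{i}" for i in range(10)]
        sets = GeneSetCollection({"s": background[:5]})
        res = hypergeom_ora(background[:5], sets, background, min_size=2)
        assert res.loc["s", "p"] == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_overlap_p_one(self):
        background = [f"b{i}" for i in range(10)]
        sets = GeneSetCollection({"s": background[:5]})
        res = hypergeom_ora(background[5:], sets, background, min_size=2)
        assert res.loc["s", "p"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(56)
        background = [f"b{i}" for i in range(12)]
        members = list(rng.choice(background, 6, replace=False))
        query = list(rng.choice(background, 5, replace=False))
        sets = GeneSetCollection({"s": members})
        res = hypergeom_ora(query, sets, background, min_size=2)
        k_obs = len(set(query) & set(members))
        # exhaustive: over all C(12, 5) draws, fraction with overlap >= k_obs
        count = sum(
            1
            for draw in itertools.combinations(background, 5)
            if len(set(draw) & set(members)) >= k_obs
        )
        from math import comb
        assert res.loc["s", "p"] == pytest.approx(count / comb(12, 5), abs=1e-12)

    def test_size_filter_applied_after_background_intersection(self):
        background = [f"b{i}" for i in range(20)]
        sets = GeneSetCollection({"s": background[:4] + ["outside1", "outside2"]})
        res = hypergeom_ora(background[:3], sets, background, min_size=5)
        assert len(res) == 0  # 4 in-background members < min_size

    def test_query_outside_background_rejected(self):
        sets = GeneSetCollection({"s": ["a", "b", "c", "d", "e"]})
        with pytest.raises(ValueError, match="alien"):
            hypergeom_ora(["alien"], sets, ["a", "b", "c", "d", "e"], min_size=2)


class TestGraph:
    @staticmethod
    def consensus_table(names, q=1e-4):
        return pd.DataFrame(
            {
                "size": 10,
                "camera_q": q,
                "gsea_q": q,
                "direction": "up",
                "consensus": True,
            },
            index=names,
        )

    def test_disjoint_sets_no_edges(self):
        sets = GeneSetCollection({"a": ["g1", "g2"], "b": ["g3", "g4"]})
        g = build_enrichment_graph(self.consensus_table(["a", "b"]), sets)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 0

    def test_subset_weight_one(self):
        sets = GeneSetCollection({"a": ["g1", "g2"], "b": ["g1", "g2", "g3"]})
        g = build_enrichment_graph(self.consensus_table(["a", "b"]), sets)
        assert g.edges[("a", "b")]["similarity"] == pytest.approx(1.0)

    def test_threshold_zero_connects_any_sharing_pair(self):
        sets = GeneSetCollection(
            {"a": ["g1", "g2"], "b": ["g2", "g3"], "c": ["g3", "g4"], "d": ["g9"]}
        )
        g = build_enrichment_graph(
            self.consensus_table(["a", "b", "c", "d"]), sets, threshold=0.0
        )
        expected = {("a", "b"), ("b", "c")}
        assert {tuple(sorted(e)) for e in g.edges} == expected

    def test_node_q_gate(self):
        sets = GeneSetCollection({"a": ["g1", "g2"], "b": ["g1", "g3"]})
        table = self.consensus_table(["a", "b"])
        table.loc["b", "gsea_q"] = 0.02  # above the node threshold
        g = build_enrichment_graph(table, sets, node_q=0.01)
        assert list(g.nodes) == ["a"]
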