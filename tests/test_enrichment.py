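import numpy as np
import pandas as pd
import pytest
from scipy import stats

import snpgsa
from snpgsa import (
    GeneSetCollection,
    cerno,
    gsea,
    gsea_snp,
    igsea4gwas,
    magenta75,
    make_ranked_list,
    ora,
    run_all,
    running_enrichment_score,
)
from snpgsa.enrichment import _es_for_sets, _membership
from snpgsa.variant_qc import SnpGeneMap

from _oracles import brute_force_es, hypergeom_upper_tail


def scores_frame(ids, p, ld=False):
    p = np.asarray(p, dtype=float)
    return pd.DataFrame(
        {
            "gene_id": list(ids),
            "method": "minimum",
            "k": 1,
            "statistic": 0.0,
            "p_gene": p,
            "ld_corrected": ld,
            "p_corr": p,
        }
    )


class TestRunningEnrichmentScore:
    def worked_list(self):
        # rank metric r = (3, 2, 1, 1, 1) via p = 10^-r
        return make_ranked_list(
            ["g1", "g2", "g3", "g4", "g5"], [1e-3, 1e-2, 0.1, 0.1, 0.1]
        )

    def test_worked_example(self):
        ranked = self.worked_list()
        es, pos, p_hit, p_miss = running_enrichment_score(ranked, {"g1", "g3"})
        assert es == pytest.approx(0.75)
        assert pos == 0
        # full prefix deviations from the definition
        devs = p_hit - p_miss
        assert devs == pytest.approx([0.75, 0.75 - 1 / 3, 1 - 1 / 3, 1 - 2 / 3, 0.0])

    def test_profiles_end_at_one(self):
        ranked = self.worked_list()
        _, _, p_hit, p_miss = running_enrichment_score(ranked, {"g2", "g5"})
        assert p_hit[-1] == pytest.approx(1.0)
        assert p_miss[-1] == pytest.approx(1.0)

    def test_degenerate_set_raises(self):
        ranked = make_ranked_list(["a", "b", "c"], [0.01, 1.0, 1.0])
        with pytest.raises(ValueError, match="degenerate"):
            running_enrichment_score(ranked, {"b", "c"})

    def test_matches_brute_force_on_random_instances(self, rng):
        for trial in range(120):
            n = int(rng.integers(3, 21))
            r = np.round(rng.uniform(0, 4, size=n), 2)
            r[rng.random(n) < 0.2] = 0.0
            ids = [f"g{i:02d}" for i in range(n)]
            p = 10.0 ** (-r)
            ranked = make_ranked_list(ids, p)
            size = int(rng.integers(1, n))
            members = set(rng.choice(ids, size=size, replace=False))
            hit = [g in members for g in ranked.ids]
            if not any(h and w > 0 for h, w in zip(hit, ranked.r)):
                continue
            es, pos, _, _ = running_enrichment_score(ranked, members)
            oracle_es, oracle_pos = brute_force_es(list(ranked.r), hit)
            assert es == pytest.approx(oracle_es, abs=1e-10)
            assert pos == oracle_pos
            assert -1.0 <= es <= 1.0

    def test_vectorized_core_agrees_with_single_set_path(self, rng):
        n = 15
        r = rng.uniform(0, 3, size=n)
        ids = np.array([f"g{i:02d}" for i in range(n)], dtype=object)
        ranked = make_ranked_list(ids, 10.0**(-r))
        sets = GeneSetCollection(
            {f"s{j}": list(rng.choice(ids, size=5, replace=False)) for j in range(6)}
        )
        names, H = _membership(sets, ranked.ids, min_set_size=1, max_is_proper=True)
        es_mat, _ = _es_for_sets(ranked.r, H)
        for name, es in zip(names, es_mat):
            single, _, _, _ = running_enrichment_score(ranked, sets.sets[name])
            assert es == pytest.approx(single, abs=1e-12)


def spiked_universe(rng, n_genes=40, spike_size=8):
    ids = [f"g{i:02d}" for i in range(n_genes)]
    p = rng.uniform(0.05, 1.0, size=n_genes)
    spiked = ids[:spike_size]
    p[:spike_size] = 1e-6
    sets = {"spiked": spiked}
    for j in range(7):
        sets[f"bg{j}"] = list(rng.choice(ids, size=spike_size, replace=False))
    return scores_frame(ids, p), GeneSetCollection(sets)


class TestGsea:
    def test_spiked_set_wins(self, rng):
        scores, sets = spiked_universe(rng)
        res = gsea(scores, sets, n_perm=200, seed=1)
        best = res.sort_values("p").iloc[0]
        assert best["set_id"] == "spiked"

    def test_determinism(self, rng):
        scores, sets = spiked_universe(rng)
        a = gsea(scores, sets, n_perm=100, seed=3)
        b = gsea(scores, sets, n_perm=100, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_permutation_p_bounds(self, rng):
        scores, sets = spiked_universe(rng)
        res = gsea(scores, sets, n_perm=100, seed=2)
        assert (res["p"] >= 1 / 101).all() and (res["p"] <= 1).all()
        assert (res["p_adj"] >= res["p"] - 1e-12).all()


class TestGseaSnp:
    def test_reduces_to_gsea_with_one_snp_per_gene(self, rng):
        # with exactly one SNP per gene and minimum integration the ranked
        # lists coincide, so ES, NES and p must match position by position
        n = 30
        genes = [f"g{i:02d}" for i in range(n)]
        snps = [f"g{i:02d}" for i in range(n)]  # same labels -> same tie-breaks
        p = rng.uniform(1e-4, 1, size=n)
        mapping = SnpGeneMap(
            gene_to_snps={g: [s] for g, s in zip(genes, snps)},
            snp_to_genes={s: [g] for g, s in zip(genes, snps)},
        )
        assoc = pd.DataFrame({"snp_id": snps, "statistic": 0.0, "p_value": p,
                              "n_effective": 10, "error": None})
        sets = GeneSetCollection(
            {f"s{j}": list(rng.choice(genes, size=6, replace=False)) for j in range(5)}
        )
        scores = snpgsa.integrate_genes(assoc, mapping, "minimum", apply_ld=False)
        res_gene = gsea(scores, sets, n_perm=150, seed=11).set_index("set_id")
        res_snp = gsea_snp(assoc, mapping, sets, n_perm=150, seed=11).set_index("set_id")
        pd.testing.assert_frame_equal(
            res_gene.drop(columns="algorithm"), res_snp.drop(columns="algorithm")
        )


class TestIgsea4Gwas:
    def make_inputs(self, rng, n_genes=40):
        genes = [f"g{i:02d}" for i in range(n_genes)]
        mapping = SnpGeneMap(
            gene_to_snps={g: [f"{g}_s{j}" for j in range(rng.integers(1, 4))] for g in genes},
            snp_to_genes={},
        )
        mapping.snp_to_genes = {
            s: [g] for g, ss in mapping.gene_to_snps.items() for s in ss
        }
        snps = [s for ss in mapping.gene_to_snps.values() for s in ss]
        p = rng.uniform(1e-5, 1, size=len(snps))
        assoc = pd.DataFrame({"snp_id": snps, "statistic": 0.0, "p_value": p,
                              "n_effective": 10, "error": None})
        sets = GeneSetCollection(
            {f"s{j}": list(rng.choice(genes, size=8, replace=False)) for j in range(6)}
        )
        return assoc, mapping, sets

    def test_spes_equals_es_times_significance_ratio(self, rng):
        assoc, mapping, sets = self.make_inputs(rng)
        res = igsea4gwas(assoc, mapping, sets, method="minimum", n_perm=50, seed=4)
        # independent recomputation of ES, k and K
        scores = snpgsa.integrate_genes(assoc, mapping, "minimum", apply_ld=False)
        ranked = snpgsa.rank_genes(scores)
        p_snp = assoc.set_index("snp_id")["p_value"]
        m_top = int(np.ceil(0.05 * len(p_snp)))
        thr = np.sort(p_snp.to_numpy())[m_top - 1]
        sig_genes = {
            g for g, ss in mapping.gene_to_snps.items()
            if min(p_snp[s] for s in ss) <= thr
        }
        big_k = len(sig_genes) / len(scores)
        for _, row in res.iterrows():
            members = set(sets.sets[row["set_id"]])
            es, _, _, _ = running_enrichment_score(ranked, members)
            small_k = len(members & sig_genes) / len(members)
            assert row["statistic"] == pytest.approx(es * small_k / big_k, abs=1e-9)

    def test_determinism(self, rng):
        assoc, mapping, sets = self.make_inputs(rng)
        a = igsea4gwas(assoc, mapping, sets, n_perm=60, seed=5)
        b = igsea4gwas(assoc, mapping, sets, n_perm=60, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_fraction_raises(self, rng):
        assoc, mapping, sets = self.make_inputs(rng)
        with pytest.raises(ValueError):
            igsea4gwas(assoc, mapping, sets, top_snp_fraction=1.5)


class TestMagenta75:
    def test_leading_edge_count(self):
        # universe tuned so the 75th percentile cutoff (0.65) splits the
        # probe set's p-values (0.01, 0.2, 0.6, 0.9) into exactly 3 hits
        ids = [f"g{i}" for i in range(8)]
        p = [0.01, 0.2, 0.6, 0.9, 0.3, 0.5, 0.62, 0.7]
        res = magenta75(
            scores_frame(ids, p), GeneSetCollection({"probe": ids[:4]}),
            n_perm=200, seed=0, min_set_size=4,
        )
        cutoff = np.percentile(p, 75)
        expected = sum(x < cutoff for x in [0.01, 0.2, 0.6, 0.9])
        assert res.iloc[0]["n_hits"] == expected == 3

    def test_whole_universe_set_gives_p_one(self, rng):
        ids = [f"g{i}" for i in range(10)]
        res = magenta75(
            scores_frame(ids, rng.uniform(size=10)),
            GeneSetCollection({"all": ids}), n_perm=300, seed=1, min_set_size=5,
        )
        assert res.iloc[0]["p"] == 1.0

    def test_null_pvalues_roughly_uniform(self, rng):
        ids = [f"g{i:03d}" for i in range(400)]
        scores = scores_frame(ids, rng.uniform(size=400))
        sets = GeneSetCollection(
            {f"s{j}": list(rng.choice(ids, size=25, replace=False)) for j in range(150)}
        )
        res = magenta75(scores, sets, n_perm=500, seed=2)
        # discrete and conservative, never anticonservative in excess
        fpr = (res["p"] < 0.05).mean()
        assert fpr <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 150)


class TestOra:
    def test_worked_hypergeometric_example(self):
        # universe 20, set 5, 4 significant genes, overlap 3 -> 155/4845
        ids = [f"g{i:02d}" for i in range(20)]
        p = np.full(20, 0.5)
        p[[0, 1, 2, 10]] = 0.01  # 4 DEGs; 3 inside the probe set
        res = ora(scores_frame(ids, p), GeneSetCollection({"probe": ids[:5]}))
        assert res.iloc[0]["p"] == pytest.approx(155 / 4845, rel=1e-12)
        assert res.iloc[0]["n_hits"] == 3

    def test_matches_explicit_sum_on_random_small_universes(self, rng):
        for _ in range(40):
            n = int(rng.integers(8, 31))
            ids = [f"g{i:02d}" for i in range(n)]
            p = rng.uniform(size=n)
            size = int(rng.integers(2, n - 1))
            members = list(rng.choice(ids, size=size, replace=False))
            res = ora(
                scores_frame(ids, p), GeneSetCollection({"s": members}),
                deg_alpha=0.3, min_set_size=2,
            )
            deg = {g for g, q in zip(ids, p) if q < 0.3}
            if not deg:
                assert res.iloc[0]["p"] == 1.0
                continue
            x = len(deg & set(members))
            oracle = hypergeom_upper_tail(x, n, size, len(deg))
            assert res.iloc[0]["p"] == pytest.approx(oracle, rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        ids = [f"g{i}" for i in range(12)]
        p = np.full(12, 0.5)
        p[6] = 0.001
        res = ora(scores_frame(ids, p), GeneSetCollection({"s": ids[:5]}))
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_no_deg_warns_and_returns_ones(self, caplog):
        ids = [f"g{i}" for i in range(12)]
        res = ora(scores_frame(ids, np.full(12, 0.9)), GeneSetCollection({"s": ids[:6]}))
        assert (res["p"] == 1.0).all()


class TestCerno:
    def test_worked_example(self):
        ids = ["g1", "g2", "g3", "g4"]
        res = cerno(
            scores_frame(ids, [0.01, 0.02, 0.6, 0.9]),
            GeneSetCollection({"top2": ["g1", "g2"]}), min_set_size=2,
        )
        f = -2 * (np.log(0.25) + np.log(0.5))
        assert res.iloc[0]["statistic"] == pytest.approx(f)
        assert res.iloc[0]["p"] == pytest.approx(stats.chi2.sf(f, 4))
        assert res.iloc[0]["p"] == pytest.approx(0.3849, abs=1e-4)

    def test_worst_rank_set_gives_p_one(self):
        ids = ["g1", "g2", "g3", "g4"]
        res = cerno(
            scores_frame(ids, [0.01, 0.02, 0.6, 0.9]),
            GeneSetCollection({"last": ["g4"]}), min_set_size=1,
        )
        assert res.iloc[0]["statistic"] == pytest.approx(0.0)
        assert res.iloc[0]["p"] == 1.0

    def test_whole_universe_statistic_depends_only_on_n(self, rng):
        ids = [f"g{i}" for i in range(9)]
        stat = []
        for _ in range(2):
            scores = scores_frame(ids, rng.uniform(size=9))
            res = cerno(scores, GeneSetCollection({"all": ids}))
            stat.append(res.iloc[0]["statistic"])
        assert stat[0] == pytest.approx(stat[1])

    def test_null_pvalues_roughly_uniform(self, rng):
        ids = [f"g{i:03d}" for i in range(400)]
        scores = scores_frame(ids, rng.uniform(size=400))
        sets = GeneSetCollection(
            {f"s{j}": list(rng.choice(ids, size=20, replace=False)) for j in range(200)}
        )
        res = cerno(scores, sets)
        assert stats.kstest(res["p"], "uniform").pvalue > 1e-4


class TestRunAll:
    def test_combination_bookkeeping_and_determinism(self, fixture_study, fixture_results):
        res = run_all(
            fixture_results["assoc"], fixture_results["mapping"], fixture_study.sets,
            n_perm=60, seed=5,
        )
        combos = res.groupby(["algorithm", "integration", "ld"]).ngroups
        # 5 integrating algorithms x 3 methods x 2 LD options + GSEA-SNP
        assert combos == 31
        again = run_all(
            fixture_results["assoc"], fixture_results["mapping"], fixture_study.sets,
            n_perm=60, seed=5,
        )
        pd.testing.assert_frame_equal(res, again)

    def test_unknown_algorithm_lists_valid_names(self, fixture_study, fixture_results):
        with pytest.raises(ValueError, match="cerno"):
            run_all(
                fixture_results["assoc"], fixture_results["mapping"],
                fixture_study.sets, algorithms=["mystery"],
            )

    def test_min_set_size_filter_drops_small_sets(self, rng):
        ids = [f"g{i:02d}" for i in range(30)]
        scores = scores_frame(ids, rng.uniform(size=30))
        sets = GeneSetCollection({"small": ids[:3], "ok": ids[:10]})
        res = cerno(scores, sets, min_set_size=5)
        assert list(res["set_id"]) == ["ok"]
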