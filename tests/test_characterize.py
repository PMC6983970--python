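import numpy as np
import pytest
from scipy import stats

from prognet.characterize import (
    hypergeom_enrich,
    mutation_expression_assoc,
    rank_importance,
    read_gmt,
    smg_cluster_enrichment,
)
from prognet.datatypes import ExpressionMatrix, MutationMatrix

from .oracles import fisher_exact_two_sided, hypergeom_upper_tail


def _expr(values, samples=None):
    values = np.atleast_2d(values)
    return ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        samples or [f"s{i}" for i in range(values.shape[1])],
        values,
    )


def _mut(row, samples, gene="SMG1"):
    return MutationMatrix([gene], samples, np.atleast_2d(row))


class TestRankImportance:
    def test_perfect_separator_ranks_first(self, rng):
        n = 60
        sep = np.concatenate([np.full(30, -2.0), np.full(30, 2.0)]) + 0.1 * rng.normal(size=n)
        vals = np.vstack([sep] + [rng.normal(size=n) for _ in range(9)])
        expr = _expr(vals)
        labels = ["C1"] * 30 + ["C2"] * 30
        ranking = rank_importance(expr, labels, n_trees=200, seed=0)
        assert ranking[0].gene_id == "g0"
        assert ranking[0].rank == 1

    def test_ranks_are_permutation(self, rng):
        expr = _expr(rng.normal(size=(6, 40)))
        labels = ["C1"] * 20 + ["C2"] * 20
        ranking = rank_importance(expr, labels, n_trees=50, seed=1)
        assert sorted(r.rank for r in ranking) == list(range(1, 7))
        imps = [r.importance for r in sorted(ranking, key=lambda r: r.rank)]
        assert all(a >= b for a, b in zip(imps, imps[1:]))

    def test_deterministic(self, rng):
        expr = _expr(rng.normal(size=(5, 30)))
        labels = ["C1"] * 15 + ["C2"] * 15
        a = rank_importance(expr, labels, n_trees=50, seed=4)
        b = rank_importance(expr, labels, n_trees=50, seed=4)
        assert [(r.gene_id, r.importance) for r in a] == [(r.gene_id, r.importance) for r in b]

    def test_duplicated_noise_gene_not_first(self, rng):
        n = 50
        sep = np.concatenate([np.full(25, -2.0), np.full(25, 2.0)])
        noise = rng.normal(size=n)
        expr = _expr(np.vstack([sep, noise, noise]))
        labels = ["C1"] * 25 + ["C2"] * 25
        ranking = rank_importance(expr, labels, n_trees=100, seed=0)
        by_gene = {r.gene_id: r.rank for r in ranking}
        assert by_gene["g1"] > 1 and by_gene["g2"] > 1

    def test_single_class_rejected(self, rng):
        expr = _expr(rng.normal(size=(3, 10)))
        with pytest.raises(ValueError):
            rank_importance(expr, ["C1"] * 10, n_trees=10, seed=0)

    def test_null_importances_small(self, rng):
        # permuted labels: top importance should be comparable to a permutation null
        expr = _expr(rng.normal(size=(8, 60)))
        hits = 0
        for seed in range(5):
            perm_rng = np.random.default_rng(seed)
            labels = list(perm_rng.permutation(["C1"] * 30 + ["C2"] * 30))
            ranking = rank_importance(expr, labels, n_trees=100, seed=seed)
            if ranking[0].importance < 0.15:  # no gene looks strongly informative
                hits += 1
        assert hits >= 4

    def test_impurity_mode(self, rng):
        n = 40
        sep = np.concatenate([np.full(20, -2.0), np.full(20, 2.0)])
        expr = _expr(np.vstack([sep, rng.normal(size=n)]))
        ranking = rank_importance(expr, ["C1"] * 20 + ["C2"] * 20,
                                  n_trees=50, seed=0, method="impurity")
        assert ranking[0].gene_id == "g0"


class TestHypergeomEnrich:
    def test_matches_enumeration_oracle(self, rng):
        universe = {f"g{i}" for i in range(18)}
        pathways = {"pw": {f"g{i}" for i in range(6)}}
        top = {f"g{i}" for i in range(0, 9, 2)} | {"g11", "g13"}
        (res,) = hypergeom_enrich(top, pathways, universe)
        oracle = hypergeom_upper_tail(res.overlap, 18, 6, len(top))
        assert res.p_value == pytest.approx(oracle, rel=1e-10)

    def test_exact_match_tiny_p(self):
        universe = {f"g{i}" for i in range(40)}
        pw = {f"g{i}" for i in range(10)}
        res = hypergeom_enrich(pw, {"pw": pw}, universe)[0]
        oracle = hypergeom_upper_tail(10, 40, 10, 10)
        assert res.p_value == pytest.approx(oracle, rel=1e-9)
        assert res.p_value < 1e-8

    def test_zero_overlap_p_near_one(self):
        universe = {f"g{i}" for i in range(100)}
        res = hypergeom_enrich({"g0", "g1"}, {"pw": {"g98", "g99"}}, universe)[0]
        assert res.p_value > 0.9

    def test_universe_equals_pathway_degenerate(self):
        universe = {f"g{i}" for i in range(10)}
        res = hypergeom_enrich({"g0", "g1", "g2"}, {"pw": set(universe)}, universe)[0]
        assert res.overlap == 3
        assert res.p_value == pytest.approx(1.0)

    def test_top_genes_must_be_in_universe(self):
        with pytest.raises(ValueError, match="outside"):
            hypergeom_enrich({"zz"}, {"pw": {"g1"}}, {"g1"})

    def test_disjoint_pathway_skipped(self):
        universe = {"g1", "g2"}
        assert hypergeom_enrich({"g1"}, {"pw": {"x1"}}, universe) == []

    def test_bh_fdr_monotone(self, rng):
        universe = {f"g{i}" for i in range(50)}
        pathways = {
            f"pw{j}": set(rng.choice(sorted(universe), size=10, replace=False))
            for j in range(8)
        }
        top = set(rng.choice(sorted(universe), size=12, replace=False))
        res = hypergeom_enrich(top, pathways, universe)
        res_sorted = sorted(res, key=lambda r: r.p_value)
        fdrs = [r.fdr for r in res_sorted]
        assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))
        assert all(r.fdr >= r.p_value - 1e-12 for r in res)


class TestReadGmt:
    def test_parse(self, tmp_path):
        gmt = tmp_path / "p.gmt"
        gmt.write_text("pathA\tdesc\tg1\tg2\tg3\npathB\turl\tg2\n\n")
        sets = read_gmt(gmt)
        assert sets == {"pathA": {"g1", "g2", "g3"}, "pathB": {"g2"}}


class TestMutationExpressionAssoc:
    def test_null_calibration(self, rng):
        n = 80
        expr = _expr(rng.normal(size=(400, n)))
        mut = _mut((rng.random(n) < 0.4).astype(int), list(expr.sample_ids))
        res = mutation_expression_assoc(expr, mut, "SMG1")
        frac = np.mean([r.p_value < 0.05 for r in res])
        assert frac == pytest.approx(0.05, abs=0.04)

    def test_planted_shift_recovered(self, rng):
        n = 200
        carrier = np.zeros(n, int)
        carrier[:100] = 1
        shifted = rng.normal(size=n) + carrier  # +1 log2 unit in mutated group
        expr = _expr(np.vstack([shifted] + [rng.normal(size=n) for _ in range(20)]))
        mut = _mut(carrier, list(expr.sample_ids))
        res = mutation_expression_assoc(expr, mut, "SMG1", scale="log2")
        r0 = next(r for r in res if r.gene_id == "g0")
        assert r0.significant
        assert r0.fold_change == pytest.approx(2.0, rel=0.3)
        assert r0.fdr < 0.1

    def test_wilcoxon_variant(self, rng):
        n = 60
        carrier = np.array([1] * 30 + [0] * 30)
        shifted = rng.normal(size=n) + 2.0 * carrier
        expr = _expr(np.vstack([shifted]))
        mut = _mut(carrier, list(expr.sample_ids))
        (res,) = mutation_expression_assoc(expr, mut, "SMG1", test="wilcoxon")
        ref = stats.mannwhitneyu(shifted[:30], shifted[30:], alternative="two-sided").pvalue
        assert res.p_value == pytest.approx(ref)

    def test_empty_group_rejected(self, rng):
        expr = _expr(rng.normal(size=(2, 10)))
        mut = _mut(np.zeros(10, int), list(expr.sample_ids))
        with pytest.raises(ValueError, match="nonempty"):
            mutation_expression_assoc(expr, mut, "SMG1")

    def test_scale_variants(self, rng):
        n = 20
        carrier = np.array([1] * 10 + [0] * 10)
        x = np.concatenate([np.full(10, 4.0), np.full(10, 2.0)]) + 0.01 * rng.normal(size=n)
        expr = _expr(np.vstack([x]))
        mut = _mut(carrier, list(expr.sample_ids))
        (ln_res,) = mutation_expression_assoc(expr, mut, "SMG1", scale="ln")
        assert ln_res.fold_change == pytest.approx(np.exp(2.0), rel=0.05)
        (lin_res,) = mutation_expression_assoc(expr, mut, "SMG1", scale="linear")
        assert lin_res.fold_change == pytest.approx(2.0, rel=0.05)


class TestSmgClusterEnrichment:
    def test_extreme_table_matches_enumeration(self):
        samples = [f"s{i}" for i in range(20)]
        row = [1] * 10 + [0] * 10
        labels = ["C1"] * 10 + ["C2"] * 10
        mut = _mut(np.array(row), samples)
        df = smg_cluster_enrichment(mut, labels)
        # Haldane-corrected OR for [[10,0],[0,10]] is 10.5^2 / 0.5^2 = 441
        assert df.odds_ratio[0] == pytest.approx(441.0)
        oracle = fisher_exact_two_sided(10, 0, 0, 10)
        assert df.p[0] == pytest.approx(oracle, rel=1e-9)

    def test_random_tables_match_enumeration(self, rng):
        samples = [f"s{i}" for i in range(16)]
        for _ in range(25):
            row = (rng.random(16) < 0.5).astype(int)
            labels = ["C1"] * 8 + ["C2"] * 8
            mut = _mut(row, samples)
            df = smg_cluster_enrichment(mut, labels)
            a = int(row[:8].sum()); b = int(row[8:].sum())
            oracle = fisher_exact_two_sided(a, b, 8 - a, 8 - b)
            assert df.p[0] == pytest.approx(oracle, rel=1e-9)

    def test_null_or_near_one(self, rng):
        ors = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            row = (r.random(200) < 0.3).astype(int)
            mut = _mut(row, [f"s{i}" for i in range(200)])
            df = smg_cluster_enrichment(mut, ["C1"] * 100 + ["C2"] * 100)
            ors.append(np.log(df.odds_ratio[0]))
        assert np.mean(ors) == pytest.approx(0.0, abs=0.25)

    def test_all_mutated_degenerate(self):
        mut = _mut(np.ones(10, int), [f"s{i}" for i in range(10)])
        df = smg_cluster_enrichment(mut, ["C1"] * 5 + ["C2"] * 5)
        assert df.p[0] == pytest.approx(1.0)
        assert np.isfinite(df.odds_ratio[0])

    def test_needs_two_clusters(self):
        mut = _mut(np.ones(4, int), ["a", "b", "c", "d"])
        with pytest.raises(ValueError):
            smg_cluster_enrichment(mut, ["C1"] * 4)
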