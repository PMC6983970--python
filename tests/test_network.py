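import itertools

import numpy as np
import pytest

from prognet.datatypes import ExpressionMatrix
from prognet.network import (
    CorrelationMatrix,
    Cpdag,
    bicor,
    bicor_matrix,
    pc_estimate,
    pc_from_ci_test,
    select_masters,
    summarize_degrees,
)
from prognet.synthetic import make_planted_truth, simulate_expression

from .conftest import build_truth
from .oracles import all_dags, bicor_reference, dseparated, random_dag, true_cpdag


def _expr_from(values):
    values = np.atleast_2d(values)
    return ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{i}" for i in range(values.shape[1])],
        values,
    )


class TestBicor:
    def test_self_correlation_one(self, rng):
        x = rng.normal(size=50)
        assert bicor(x, x) == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        x = rng.normal(size=50)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_matches_reference_on_random_fixtures(self, rng):
        for _ in range(100):
            n = rng.integers(10, 60)
            x = rng.normal(size=n) + rng.standard_cauchy(size=n) * (rng.random() < 0.3)
            y = rng.normal(size=n)
            assert bicor(x, y) == pytest.approx(bicor_reference(x, y), abs=1e-12)

    def test_close_to_pearson_on_gaussian(self, rng):
        cov = [[1, 0.5], [0.5, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=2000)
        b = bicor(xy[:, 0], xy[:, 1])
        p = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
        assert b == pytest.approx(p, abs=0.06)

    def test_monotone_affine_invariance(self, rng):
        x = rng.normal(size=80)
        y = rng.normal(size=80) + 0.5 * x
        base = bicor(x, y)
        assert bicor(2.5 * x + 7, y) == pytest.approx(base, abs=1e-12)
        assert bicor(-2.5 * x + 7, y) == pytest.approx(-base, abs=1e-12)

    def test_robust_to_outlier(self, rng):
        x = rng.normal(size=200)
        y = 0.8 * x + 0.3 * rng.normal(size=200)
        x_out = x.copy()
        x_out[0] = 1000.0
        assert abs(bicor(x_out, y) - bicor(x, y)) < 0.05
        assert abs(np.corrcoef(x_out, y)[0, 1] - np.corrcoef(x, y)[0, 1]) > 0.2

    def test_zero_mad_fallback(self, rng):
        # >50% identical values force MAD = 0 for both vectors; the fallback
        # mean-centers both sides, so bicor degrades to exactly Pearson
        x = np.concatenate([np.zeros(30), rng.normal(size=10)])
        y = np.concatenate([np.zeros(30), 0.5 * x[30:] + rng.normal(size=10)])
        assert bicor(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)


class TestBicorMatrix:
    def test_structure(self, rng):
        expr = _expr_from(rng.normal(size=(6, 40)))
        corr = bicor_matrix(expr)
        v = corr.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert np.all(np.abs(v) <= 1.0)

    def test_matches_pairwise_reference(self, rng):
        expr = _expr_from(rng.normal(size=(5, 30)))
        corr = bicor_matrix(expr)
        for i, j in itertools.combinations(range(5), 2):
            ref = bicor_reference(expr.values[i], expr.values[j])
            assert corr.values[i, j] == pytest.approx(ref, abs=1e-12)

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match="4 samples"):
            bicor_matrix(_expr_from(rng.normal(size=(3, 3))))


class TestPcOracle:
    def test_exhaustive_four_nodes(self):
        nodes = list(range(4))
        for edges in all_dags(4):
            ci = lambda x, y, S: dseparated(nodes, edges, x, y, set(S))
            cp = pc_from_ci_test(nodes, ci)
            td, tu = true_cpdag(nodes, edges)
            assert cp.directed_edges == td, f"DAG {edges}"
            assert cp.undirected_edges == tu, f"DAG {edges}"

    @pytest.mark.parametrize("seed", range(4))
    def test_random_six_node_dags(self, seed):
        rng = np.random.default_rng(seed)
        nodes = list(range(6))
        for _ in range(25):
            edges = random_dag(6, 0.3, rng)
            ci = lambda x, y, S: dseparated(nodes, edges, x, y, set(S))
            cp = pc_from_ci_test(nodes, ci)
            td, tu = true_cpdag(nodes, edges)
            assert (cp.directed_edges, cp.undirected_edges) == (td, tu), f"DAG {edges}"


class TestPcEstimate:
    def test_diagonal_corr_empty_graph(self):
        corr = CorrelationMatrix(["a", "b", "c"], np.eye(3))
        cp = pc_estimate(corr, 100)
        assert not cp.directed_edges and not cp.undirected_edges

    def test_chain_skeleton(self, rng):
        n = 5000
        a = rng.normal(size=n)
        b = 0.8 * a + rng.normal(size=n)
        c = 0.8 * b + rng.normal(size=n)
        expr = ExpressionMatrix(["A", "B", "C"], [f"s{i}" for i in range(n)], np.vstack([a, b, c]))
        cp = pc_estimate(bicor_matrix(expr), n)
        assert cp.skeleton == {frozenset({"A", "B"}), frozenset({"B", "C"})}

    def test_collider_oriented(self):
        rng = np.random.default_rng(7)
        n = 5000
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        c = 0.7 * a + 0.7 * b + rng.normal(size=n)
        expr = ExpressionMatrix(["A", "B", "C"], [f"s{i}" for i in range(n)], np.vstack([a, b, c]))
        cp = pc_estimate(bicor_matrix(expr), n)
        assert cp.directed_edges == {("A", "C"), ("B", "C")}

    def test_invalid_alpha(self):
        corr = CorrelationMatrix(["a", "b"], np.eye(2))
        with pytest.raises(ValueError, match="alpha"):
            pc_estimate(corr, 50, alpha=0.0)

    def test_gene_order_invariance(self, rng):
        truth = make_planted_truth(n_samples=400, n_hubs=3, children_per_hub=4, seed=0,
                                   subtype_effect=0.0)
        expr = simulate_expression(truth, seed=1)
        cp1 = pc_estimate(bicor_matrix(expr), expr.n_samples)
        perm = rng.permutation(expr.n_genes)
        shuffled = ExpressionMatrix(
            [expr.gene_ids[i] for i in perm], list(expr.sample_ids), expr.values[perm]
        )
        cp2 = pc_estimate(bicor_matrix(shuffled), expr.n_samples)
        assert cp1.skeleton == cp2.skeleton


class TestCpdag:
    def test_rejects_two_cycle(self):
        with pytest.raises(ValueError, match="2-cycle"):
            Cpdag(["a", "b"], {("a", "b"), ("b", "a")}, set())

    def test_rejects_double_classification(self):
        with pytest.raises(ValueError, match="both"):
            Cpdag(["a", "b"], {("a", "b")}, {("a", "b")})

    def test_edge_tsv_roundtrip(self, tmp_path):
        cp = Cpdag(["a", "b", "c"], {("a", "b")}, {frozenset(("b", "c"))})
        cp.to_edge_tsv(tmp_path / "e.tsv")
        back = Cpdag.from_edge_tsv(tmp_path / "e.tsv", nodes=["a", "b", "c"])
        assert back.directed_edges == cp.directed_edges
        assert back.undirected_edges == cp.undirected_edges


class TestDegrees:
    def test_star_out_hub(self):
        spokes = [f"n{i}" for i in range(7)]
        cp = Cpdag(["hub"] + spokes, {("hub", s) for s in spokes}, set())
        summ = {s.gene_id: s for s in summarize_degrees(cp, 5)}
        assert summ["hub"].summarized_degree == 7
        assert summ["hub"].is_master
        assert not summ["n0"].is_master

    def test_balanced_node_not_master(self):
        nodes = ["x", "a", "b", "c", "d", "e", "f"]
        directed = {("a", "x"), ("b", "x"), ("c", "x"), ("x", "d"), ("x", "e"), ("x", "f")}
        cp = Cpdag(nodes, directed, set())
        summ = {s.gene_id: s for s in summarize_degrees(cp, 5)}
        assert summ["x"].summarized_degree == 0
        assert not summ["x"].is_master

    def test_undirected_edges_contribute_zero(self):
        cp = Cpdag(["a", "b"], set(), {frozenset(("a", "b"))})
        for s in summarize_degrees(cp):
            assert s.summarized_degree == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_degree_conservation_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        nodes = list(range(12))
        edges = random_dag(12, 0.3, rng)
        directed, undirected = true_cpdag(nodes, edges)
        cp = Cpdag(nodes, directed, undirected)
        assert sum(s.summarized_degree for s in summarize_degrees(cp)) == 0


class TestSelectMasters:
    def test_empty_when_all_zero(self):
        cp = Cpdag(["a", "b"], set(), {frozenset(("a", "b"))})
        assert select_masters(summarize_degrees(cp, 0)) == []

    def test_threshold_zero_everything_nonzero(self):
        cp = Cpdag(["a", "b", "c"], {("a", "b"), ("a", "c")}, set())
        masters = select_masters(summarize_degrees(cp, 0))
        assert set(masters) == {"a", "b", "c"}
        assert masters[0] == "a"  # |degree| 2 sorts first

    def test_tie_break_lexicographic(self):
        cp = Cpdag(["z", "y", "p", "q"], {("z", "p"), ("y", "q")}, set())
        masters = select_masters(summarize_degrees(cp, 0))
        assert masters == ["p", "q", "y", "z"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_masters([])

    def test_planted_hub_recovery(self):
        recalls = []
        for seed in range(3):
            truth = make_planted_truth(n_samples=2000, children_per_hub=5,
                                       subtype_effect=0.0, seed=seed)
            expr = simulate_expression(truth, seed=seed + 50)
            cp = pc_estimate(bicor_matrix(expr), expr.n_samples)
            masters = select_masters(summarize_degrees(cp, 4))
            recalls.append(len(set(masters) & truth.master_genes) / len(truth.master_genes))
        assert np.mean(recalls) >= 7 / 8


class TestSkeletonF1Monotone:
    def test_f1_nondecreasing_in_n(self):
        sizes = [250, 500, 1000, 2000]
        f1s = {n: [] for n in sizes}
        for seed in range(20):
            truth = make_planted_truth(n_samples=max(sizes), children_per_hub=3,
                                       n_hubs=4, subtype_effect=0.0, seed=seed)
            expr_full = simulate_expression(truth, seed=seed + 200)
            true_skel = {frozenset(e) for e in truth.dag.edges}
            for n in sizes:
                sub = expr_full.subset_samples(expr_full.sample_ids[:n])
                cp = pc_estimate(bicor_matrix(sub), n)
                est = cp.skeleton
                tp = len(est & true_skel)
                prec = tp / len(est) if est else 0.0
                rec = tp / len(true_skel)
                f1s[n].append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        means = [np.mean(f1s[n]) for n in sizes]
        assert all(b >= a - 0.005 for a, b in zip(means, means[1:])), means
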