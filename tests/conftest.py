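import networkx as nx
import numpy as np
import pytest

from prognet.datatypes import ExpressionMatrix, SurvivalTable
from prognet.synthetic import GroundTruth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_truth(edges, masters=(), labels=None, n_samples=20, betas=None,
                subtype_effect=0.0, noise_sd=1.0, weight=1.0, **kw):
    """Small hand-rolled GroundTruth for unit tests."""
    dag = nx.DiGraph()
    nodes = sorted({u for e in edges for u in e[:2]}) or ["A"]
    dag.add_nodes_from(nodes)
    weights = {}
    for e in edges:
        u, v = e[0], e[1]
        w = e[2] if len(e) > 2 else weight
        dag.add_edge(u, v)
        weights[(u, v)] = w
    if labels is None:
        labels = {f"s{i}": ("C1" if i % 2 == 0 else "C2") for i in range(n_samples)}
    return GroundTruth(
        dag=dag,
        edge_weights=weights,
        master_genes=set(masters),
        subtype_labels=labels,
        subtype_effect=subtype_effect,
        cox_betas=betas or {},
        noise_sd=noise_sd,
        **kw,
    )


@pytest.fixture
def small_expr(rng):
    vals = rng.normal(size=(5, 12))
    return ExpressionMatrix([f"g{i}" for i in range(5)], [f"s{i}" for i in range(12)], vals)


@pytest.fixture
def small_surv(rng):
    n = 12
    return SurvivalTable(
        [f"s{i}" for i in range(n)],
        rng.exponential(scale=100.0, size=n) + 1.0,
        (rng.random(n) < 0.8).astype(int),
    )
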