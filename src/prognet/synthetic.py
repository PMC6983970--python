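"""Synthetic data generation with planted ground truth.

Expression follows a linear-Gaussian structural equation model over a known
DAG; designated hub ("master") genes get an additive subtype shift; survival
times come from a Weibull proportional-hazards model driven by per-gene
log-hazard coefficients; mutations are Bernoulli with a subtype-dependent
odds ratio. Every generator is deterministic under its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .datatypes import ExpressionMatrix, MutationMatrix, SurvivalTable

__all__ = [
    "GroundTruth",
    "make_planted_truth",
    "simulate_expression",
    "simulate_survival",
    "simulate_mutations",
]

log = logging.getLogger(__name__)


@dataclass
class GroundTruth:
    """Planted generative structure against which recovery is scored.

    ``dag`` edges carry linear weights via ``edge_weights``; ``master_genes``
    are the designated hubs that receive the additive ``subtype_effect`` in
    C1 samples; ``cox_betas`` are per-gene log-hazard coefficients (genes not
    listed have beta 0); ``mutated_gene_sets`` optionally pins the mutated
    sample set per SMG (otherwise :func:`simulate_mutations` draws them);
    ``mutation_targets`` maps SMG id -> {gene id: expression shift applied to
    mutated samples during generation}.
    """

    dag: nx.DiGraph
    edge_weights: dict[tuple[str, str], float]
    master_genes: set[str]
    subtype_labels: dict[str, str]
    subtype_effect: float
    cox_betas: dict[str, float]
    noise_sd: float = 1.0
    subtype_effect_signs: dict[str, float] = field(default_factory=dict)
    smg_ids: list[str] = field(default_factory=list)
    mutation_base_rate: float = 0.2
    mutation_cluster_or: float = 1.0
    mutated_gene_sets: dict[str, set[str]] | None = None
    mutation_targets: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("ground-truth graph must be acyclic")
        for u, v in self.dag.edges:
            if (u, v) not in self.edge_weights:
                raise ValueError(f"edge ({u}, {v}) missing a weight")
        for g in self.master_genes:
            if g not in self.dag.nodes:
                raise ValueError(f"master gene {g!r} is not a dag node")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for g, b in self.cox_betas.items():
            if not np.isfinite(b):
                raise ValueError(f"cox beta for {g!r} is not finite")
        bad = set(self.subtype_labels.values()) - {"C1", "C2"}
        if bad:
            raise ValueError(f"subtype labels must be C1/C2, got {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.subtype_labels)

    @property
    def network_genes(self) -> list[str]:
        return list(nx.topological_sort(self.dag))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "edges": [[u, v, self.edge_weights[(u, v)]] for u, v in self.dag.edges],
            "nodes": list(self.dag.nodes),
            "master_genes": sorted(self.master_genes),
            "subtype_labels": self.subtype_labels,
            "subtype_effect": self.subtype_effect,
            "cox_betas": self.cox_betas,
            "noise_sd": self.noise_sd,
            "subtype_effect_signs": self.subtype_effect_signs,
            "smg_ids": self.smg_ids,
            "mutation_base_rate": self.mutation_base_rate,
            "mutation_cluster_or": self.mutation_cluster_or,
            "mutated_gene_sets": (
                {k: sorted(v) for k, v in self.mutated_gene_sets.items()}
                if self.mutated_gene_sets is not None
                else None
            ),
            "mutation_targets": self.mutation_targets,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        dag = nx.DiGraph()
        dag.add_nodes_from(payload["nodes"])
        weights = {}
        for u, v, w in payload["edges"]:
            dag.add_edge(u, v)
            weights[(u, v)] = float(w)
        mgs = payload["mutated_gene_sets"]
        return cls(
            dag=dag,
            edge_weights=weights,
            master_genes=set(payload["master_genes"]),
            subtype_labels=payload["subtype_labels"],
            subtype_effect=payload["subtype_effect"],
            cox_betas={k: float(v) for k, v in payload["cox_betas"].items()},
            noise_sd=payload["noise_sd"],
            subtype_effect_signs=payload.get("subtype_effect_signs", {}),
            smg_ids=payload["smg_ids"],
            mutation_base_rate=payload["mutation_base_rate"],
            mutation_cluster_or=payload["mutation_cluster_or"],
            mutated_gene_sets={k: set(v) for k, v in mgs.items()} if mgs is not None else None,
            mutation_targets=payload["mutation_targets"],
        )

    def write_dag_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v in self.dag.edges:
                fh.write(f"{u}\t{v}\t{self.edge_weights[(u, v)]}\n")


def make_planted_truth(
    n_samples: int = 300,
    n_hubs: int = 8,
    children_per_hub: int = 8,
    feeders_per_hub: int = 2,
    subtype_effect: float = 2.0,
    hub_beta: float = 0.45,
    child_beta: float = 0.0,
    n_unfavourable_hubs: int = 6,
    edge_weight: float = 0.7,
    noise_sd: float = 1.0,
    n_smgs: int = 6,
    mutation_base_rate: float = 0.2,
    mutation_cluster_or: float = 4.0,
    mutation_expr_shift: float = 1.0,
    seed: int = 0,
) -> GroundTruth:
    """Build the canonical planted scenario.

    Each hub parents ``feeders_per_hub`` single-parent "feeder" genes and
    ``children_per_hub`` collider children whose second parent is a feeder of
    a *different* hub. Colliders are therefore unshielded (the two parents
    are conditionally independent given the feeder's own hub), which makes
    every hub -> child edge orientable by the v-structure step. Only hubs
    carry hazard coefficients (sign-imbalanced so the subtype shift produces
    a net survival difference); feeders and children inherit prognostic
    relevance through their hub, keeping the linear-predictor variance low.
    SMG mutations are enriched in C1 and each shifts one hub's first child.
    """
    rng = np.random.default_rng(seed)
    n_children = n_hubs * children_per_hub
    n_feeders = n_hubs * feeders_per_hub
    hubs = [f"HUB{i:02d}" for i in range(n_hubs)]
    feeders = [f"FDR{i:02d}" for i in range(n_feeders)]
    children = [f"CHD{i:03d}" for i in range(n_children)]
    feeder_owner = {f: hubs[i // feeders_per_hub] for i, f in enumerate(feeders)}

    hub_sign = {h: (1.0 if i < n_unfavourable_hubs else -1.0) for i, h in enumerate(hubs)}
    # shift signs must be mixed (correlation-based sample distance is blind to
    # a uniform-direction signature) while keeping sum(beta * sign) > 0 so C1
    # still has worse survival
    effect_signs = {h: (1.0 if i < n_hubs // 2 else -1.0) for i, h in enumerate(hubs)}
    # a child's marginal survival association is the sum of its two parents'
    # contributions; pair each child with a feeder whose owner hub pulls in
    # the same direction so the contributions never cancel below the screen
    # threshold
    direction = effect_signs if subtype_effect != 0.0 else hub_sign
    counts = {s: sum(1 for h in hubs if direction[h] == s) for s in (1.0, -1.0)}
    if min(counts.values(), default=0) == 1 or len(hubs) < 2:
        direction = {h: 1.0 for h in hubs}  # too few hubs to pair within groups

    dag = nx.DiGraph()
    dag.add_nodes_from(hubs + feeders + children)
    weights: dict[tuple[str, str], float] = {}
    for f in feeders:
        dag.add_edge(feeder_owner[f], f)
        weights[(feeder_owner[f], f)] = edge_weight
    cursor = 0
    for ci, child in enumerate(children):
        hub = hubs[ci // children_per_hub]
        while (feeder_owner[feeders[cursor % n_feeders]] == hub
               or direction[feeder_owner[feeders[cursor % n_feeders]]] != direction[hub]):
            cursor += 1
        feeder = feeders[cursor % n_feeders]
        cursor += 1
        for parent in (hub, feeder):
            dag.add_edge(parent, child)
            weights[(parent, child)] = edge_weight

    betas = {h: hub_beta * hub_sign[h] for h in hubs}
    for ci, child in enumerate(children):
        if child_beta:
            betas[child] = child_beta * hub_sign[hubs[ci // children_per_hub]]

    samples = [f"S{i:04d}" for i in range(n_samples)]
    labels = {s: ("C1" if rng.random() < 0.5 else "C2") for s in samples}

    smgs = [f"SMG{i:02d}" for i in range(n_smgs)]
    targets = {
        smg: {children[(i % n_hubs) * children_per_hub]: mutation_expr_shift}
        for i, smg in enumerate(smgs)
    }

    return GroundTruth(
        dag=dag,
        edge_weights=weights,
        master_genes=set(hubs),
        subtype_labels=labels,
        subtype_effect=subtype_effect,
        cox_betas=betas,
        noise_sd=noise_sd,
        subtype_effect_signs=effect_signs,
        smg_ids=smgs,
        mutation_base_rate=mutation_base_rate,
        mutation_cluster_or=mutation_cluster_or,
        mutation_targets=targets,
    )


def simulate_expression(
    truth: GroundTruth,
    n_samples: int | None = None,
    seed: int = 0,
    n_background: int = 0,
    mutations: MutationMatrix | None = None,
) -> ExpressionMatrix:
    """Draw a log-scale expression matrix from the planted structural model.

    Genes are generated in topological order: each equals the weighted sum of
    its parents plus N(0, noise_sd^2) noise; master genes additionally get
    ``subtype_effect`` (times the per-gene sign in ``subtype_effect_signs``)
    added in C1 samples, and mutation target genes get their shift in
    mutated samples. Shifts enter the structural equations, so they propagate
    to downstream genes — the latent subtype behaves like an extra exogenous
    parent of the master genes. ``n_background`` pure-noise genes
    (``BGxxxx``) are appended.
    """
    if n_samples is not None and n_samples != len(truth.subtype_labels):
        raise ValueError("n_samples must match the ground-truth subtype labels")
    samples = truth.samples
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng(seed)

    c1_mask = np.array([truth.subtype_labels[s] == "C1" for s in samples])
    mut_shift = {}
    if mutations is not None:
        mcols = {s: i for i, s in enumerate(mutations.sample_ids)}
        for smg, tgt in truth.mutation_targets.items():
            if smg not in mutations.gene_ids:
                continue
            row = mutations.values[mutations.gene_ids.index(smg)]
            mask = np.array([bool(row[mcols[s]]) if s in mcols else False for s in samples])
            for gene, shift in tgt.items():
                mut_shift.setdefault(gene, np.zeros(n))
                mut_shift[gene] += shift * mask

    order = truth.network_genes
    values = {}
    for gene in order:
        x = rng.normal(0.0, truth.noise_sd, size=n)
        for parent in truth.dag.predecessors(gene):
            x = x + truth.edge_weights[(parent, gene)] * values[parent]
        if gene in truth.master_genes:
            sign = truth.subtype_effect_signs.get(gene, 1.0)
            x = x + sign * truth.subtype_effect * c1_mask
        if gene in mut_shift:
            x = x + mut_shift[gene]
        values[gene] = x

    gene_ids = list(order)
    rows = [values[g] for g in order]
    for i in range(n_background):
        gene_ids.append(f"BG{i:04d}")
        rows.append(rng.normal(0.0, truth.noise_sd, size=n))
    mat = np.vstack(rows) if rows else np.empty((0, n))
    return ExpressionMatrix(gene_ids, samples, mat)


def simulate_survival(
    expr: ExpressionMatrix,
    truth: GroundTruth,
    baseline_scale: float = 365.0,
    censor_rate: float = 0.3,
    shape: float = 1.0,
    seed: int = 0,
) -> SurvivalTable:
    """Draw survival times from a Weibull proportional-hazards model.

    The linear predictor is sum_g cox_betas[g] * expr[g, sample] (centered
    per gene so the baseline scale is interpretable). Censoring times are
    uniform on (0, q) with q calibrated by bisection so the expected censored
    fraction matches ``censor_rate``; they are independent of event times.
    """
    if baseline_scale <= 0:
        raise ValueError("baseline_scale must be positive")
    if not 0.0 <= censor_rate <= 1.0:
        raise ValueError("censor_rate must lie in [0, 1]")
    if set(expr.sample_ids) - set(truth.subtype_labels):
        raise ValueError("expression samples missing from ground-truth labels")
    rng = np.random.default_rng(seed)
    n = expr.n_samples

    lp = np.zeros(n)
    for gene, beta in truth.cox_betas.items():
        if beta == 0.0 or gene not in expr.gene_ids:
            continue
        row = expr.values[expr.gene_ids.index(gene)]
        lp += beta * (row - row.mean())

    # Weibull PH: T = scale * (E / exp(lp))**(1/shape), E ~ Exp(1)
    e = rng.exponential(size=n)
    t_event = baseline_scale * (e / np.exp(lp)) ** (1.0 / shape)
    t_event = np.maximum(t_event, 1e-9)

    if censor_rate <= 0.0:
        return SurvivalTable(list(expr.sample_ids), t_event, np.ones(n, dtype=int))
    if censor_rate >= 1.0:
        t_obs = t_event * rng.uniform(0.5, 0.999, size=n)
        return SurvivalTable(list(expr.sample_ids), np.maximum(t_obs, 1e-12), np.zeros(n, dtype=int))

    # expected censored fraction with C ~ U(0, q): mean_i min(t_i/q, 1)
    def frac_censored(q: float) -> float:
        return float(np.mean(np.minimum(t_event / q, 1.0)))

    lo, hi = np.min(t_event) * 1e-6, np.max(t_event) * 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac_censored(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    q = np.sqrt(lo * hi)
    c = rng.uniform(0.0, q, size=n)
    event = (t_event <= c).astype(int)
    t_obs = np.minimum(t_event, c)
    return SurvivalTable(list(expr.sample_ids), np.maximum(t_obs, 1e-12), event)


def simulate_mutations(
    truth: GroundTruth,
    samples: list[str] | None = None,
    seed: int = 0,
) -> MutationMatrix:
    """Draw the binary SMG x sample mutation matrix.

    If ``truth.mutated_gene_sets`` is set those sample sets are materialized
    verbatim; otherwise each SMG is Bernoulli per sample with C2 probability
    ``mutation_base_rate`` and C1 probability realizing
    ``mutation_cluster_or`` on the odds scale.
    """
    if samples is None:
        samples = truth.samples
    if not samples:
        raise ValueError("samples must be nonempty")
    unknown = set(samples) - set(truth.subtype_labels)
    if unknown:
        raise ValueError(f"unknown sample ids: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)

    if truth.mutated_gene_sets is not None:
        genes = sorted(truth.mutated_gene_sets)
        mat = np.zeros((len(genes), len(samples)), dtype=int)
        for gi, g in enumerate(genes):
            carriers = truth.mutated_gene_sets[g]
            mat[gi] = [1 if s in carriers else 0 for s in samples]
        return MutationMatrix(genes, list(samples), mat)

    p2 = truth.mutation_base_rate
    if p2 <= 0:
        p1 = 0.0
    else:
        odds1 = truth.mutation_cluster_or * p2 / (1.0 - p2)
        p1 = odds1 / (1.0 + odds1)
    c1 = np.array([truth.subtype_labels[s] == "C1" for s in samples])
    probs = np.where(c1, p1, p2)
    mat = np.zeros((len(truth.smg_ids), len(samples)), dtype=int)
    for gi in range(len(truth.smg_ids)):
        mat[gi] = (rng.random(len(samples)) < probs).astype(int)
    return MutationMatrix(list(truth.smg_ids), list(samples), mat)
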