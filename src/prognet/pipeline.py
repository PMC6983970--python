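"""End-to-end orchestration: screen -> network -> subtype -> characterize -> predict.

A single JSON config drives the run; every stage writes its artifact TSVs
stamped with the config hash, and a manifest records per-stage counts so a
run is fully reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .characterize import (
    associations_to_tsv,
    enrichment_to_tsv,
    hypergeom_enrich,
    importance_to_tsv,
    mutation_expression_assoc,
    rank_importance,
    read_gmt,
    smg_cluster_enrichment,
)
from .datatypes import ExpressionMatrix, MutationMatrix, SurvivalTable
from .network import bicor_matrix, degrees_to_tsv, pc_estimate, select_masters, summarize_degrees
from .predictor import fit_predictor, loocv_accuracy, transfer_labels
from .screen import compare_groups, cox_screen, filter_zero_heavy, select_network_genes, write_results
from .subtype import consensus_cluster, random_gene_null, zscore_genes
from .synthetic import make_planted_truth, simulate_expression, simulate_mutations, simulate_survival

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "run_demo"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    expr_path: str
    clinical_path: str
    out_dir: str
    mutations_path: str | None = None
    pathways_path: str | None = None
    smg_list: list[str] = field(default_factory=list)
    zero_frac: float = 0.7
    screen_p: float = 0.05
    standardize: bool = False
    network_p: float = 0.01
    min_abs_coef: float = 0.2
    pc_alpha: float = 0.01
    pc_max_cond: int | None = None
    hub_threshold: int = 5
    k: int = 2
    consensus_reps: int = 100
    item_frac: float = 0.8
    null_reps: int = 100
    null_consensus_reps: int = 100
    null_gene_source: str = "masters"  # masters | network (count of random genes per draw)
    top_n_importance: int = 50
    top_n_predictor: int = 10
    n_trees: int = 500
    assoc_fdr: float = 0.1
    assoc_test: str = "t"
    expression_scale: str = "log2"  # log2 | ln | linear
    predictor_alpha_grid: list[float] = field(default_factory=lambda: [0.25, 0.5, 0.75, 1.0])
    predictor_lambda_grid: list[float] = field(default_factory=lambda: list(np.logspace(-4, 0, 20)))
    run_loocv: bool = True
    external_expr_path: str | None = None
    external_clinical_path: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for name, val, lo, hi in [
            ("zero_frac", self.zero_frac, 0, 1),
            ("screen_p", self.screen_p, 0, 1),
            ("network_p", self.network_p, 0, 1),
            ("pc_alpha", self.pc_alpha, 0, 1),
            ("item_frac", self.item_frac, 0, 1),
            ("assoc_fdr", self.assoc_fdr, 0, 1),
        ]:
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
        if self.k < 2 or self.null_reps < 1 or self.hub_threshold < 0:
            raise ValueError("invalid threshold configuration")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        d.update(overrides)
        return cls(**d)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order, returning (and writing) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stamp = f"config_hash={chash}"
    manifest: dict = {
        "prognet_version": __version__,
        "config": asdict(config),
        "config_hash": chash,
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                counts = fn()
            except Exception as exc:  # retain partial outputs, name the stage
                _write_manifest(manifest, out)
                raise PipelineError(name, exc) from exc
            counts["seconds"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][name] = counts
            log.info("stage %s: %s", name, counts)
            return counts

        return deco

    state: dict = {}

    @stage("screen")
    def _screen():
        expr = ExpressionMatrix.from_tsv(config.expr_path)
        surv = SurvivalTable.from_tsv(config.clinical_path)
        expr = filter_zero_heavy(expr, config.zero_frac)
        results = cox_screen(expr, surv, p_threshold=config.screen_p, standardize=config.standardize)
        write_results(results, out / "screen_results.tsv", stamp)
        network_genes = select_network_genes(results, config.network_p, config.min_abs_coef)
        (out / "network_genes.txt").write_text("\n".join(network_genes) + "\n")
        state.update(expr=expr, surv=surv.align(expr.sample_ids) if set(expr.sample_ids) <= set(surv.sample_ids) else surv, results=results, network_genes=network_genes)
        relevant = sum(r.direction != "none" for r in results)
        return {
            "genes_after_zero_filter": expr.n_genes,
            "samples": expr.n_samples,
            "prognosis_relevant": relevant,
            "network_genes": len(network_genes),
        }

    @stage("network")
    def _network():
        genes = state["network_genes"]
        if len(genes) < 2:
            raise ValueError("fewer than 2 network genes selected; cannot build a network")
        sub = state["expr"].subset_genes(genes)
        corr = bicor_matrix(sub)
        cpdag = pc_estimate(corr, sub.n_samples, alpha=config.pc_alpha, max_cond_size=config.pc_max_cond)
        cpdag.to_edge_tsv(out / "cpdag_edges.tsv", stamp)
        summaries = summarize_degrees(cpdag, config.hub_threshold)
        degrees_to_tsv(summaries, out / "degree_summary.tsv", stamp)
        masters = select_masters(summaries)
        (out / "master_genes.txt").write_text("\n".join(masters) + "\n")
        state.update(cpdag=cpdag, masters=masters)
        return {
            "directed_edges": len(cpdag.directed_edges),
            "undirected_edges": len(cpdag.undirected_edges),
            "masters": len(masters),
        }

    @stage("subtype")
    def _subtype():
        masters = state["masters"]
        if not masters:
            raise ValueError("master gene list is empty; subtype stage cannot run")
        expr, surv = state["expr"], state["surv"]
        surv = surv.align(expr.sample_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaled = zscore_genes(expr.subset_genes(masters))
        res = consensus_cluster(
            scaled, k=config.k, n_reps=config.consensus_reps,
            item_frac=config.item_frac, seed=config.seed, surv=surv,
        )
        res.write_labels(out / "subtype_labels.tsv", stamp)
        res.write_consensus(out / "consensus_matrix.tsv", stamp)
        n_null_genes = len(masters) if config.null_gene_source == "masters" else len(state["network_genes"])
        n_null_genes = min(n_null_genes, expr.n_genes)
        observed = -np.log10(res.logrank_p) if res.logrank_p > 0 else float("inf")
        null = random_gene_null(
            expr, surv, n_genes=n_null_genes, n_reps=config.null_reps,
            seed=config.seed + 1, consensus_reps=config.null_consensus_reps,
            item_frac=config.item_frac, observed_neglog10_p=observed,
        )
        null.to_tsv(out / "null_distribution.tsv", stamp)
        state.update(subtypes=res, null=null, scaled_masters=scaled)
        return {
            "cluster_sizes": list(res.cluster_sizes),
            "logrank_p": res.logrank_p,
            "null_reps": null.n_reps,
            "null_genes_per_rep": null.genes_per_rep,
            "empirical_null_p": null.empirical_p(),
        }

    @stage("characterize")
    def _characterize():
        res = state["subtypes"]
        scaled = state["scaled_masters"]
        ranking = rank_importance(scaled, res.labels, n_trees=config.n_trees, seed=config.seed)
        importance_to_tsv(ranking, out / "importance_ranking.tsv", stamp)
        counts = {"ranked_genes": len(ranking)}
        if config.pathways_path:
            pathways = read_gmt(config.pathways_path)
            universe = set(state["expr"].gene_ids) & set().union(*pathways.values())
            top = {r.gene_id for r in ranking[: config.top_n_importance]} & universe
            enr = hypergeom_enrich(top, pathways, universe)
            enrichment_to_tsv(enr, out / "pathway_enrichment.tsv", stamp)
            counts["pathways_tested"] = len(enr)
        if config.mutations_path:
            mut = MutationMatrix.from_tsv(config.mutations_path)
            smgs = config.smg_list or list(mut.gene_ids)
            enrich = smg_cluster_enrichment(mut, {s: res.labels[s] for s in mut.sample_ids})
            enrich.to_csv(out / "smg_cluster_enrichment.tsv", sep="\t", index=False)
            assoc_all = []
            for smg in smgs:
                try:
                    assoc_all.extend(
                        mutation_expression_assoc(
                            state["expr"], mut, smg, test=config.assoc_test,
                            scale=config.expression_scale, fdr_threshold=config.assoc_fdr,
                        )
                    )
                except ValueError as exc:
                    log.warning("association for %s skipped: %s", smg, exc)
            associations_to_tsv(assoc_all, out / "mutation_associations.tsv", stamp)
            counts["smgs_tested"] = len(smgs)
            counts["significant_associations"] = sum(a.significant for a in assoc_all)
        state["ranking"] = ranking
        return counts

    @stage("predict")
    def _predict():
        ranking = state["ranking"]
        res = state["subtypes"]
        top = [r.gene_id for r in ranking[: config.top_n_predictor]]
        expr = state["expr"]
        model = fit_predictor(
            expr, res.labels, top,
            alpha_grid=config.predictor_alpha_grid,
            lambda_grid=config.predictor_lambda_grid,
            seed=config.seed,
        )
        model.to_json(out / "predictor.json")
        counts = {"predictor_genes": len(top), "alpha": model.alpha, "lambda": model.lam}
        if config.run_loocv:
            counts["loocv_accuracy"] = loocv_accuracy(
                expr, res.labels, top,
                alpha_grid=config.predictor_alpha_grid,
                lambda_grid=config.predictor_lambda_grid,
                seed=config.seed,
            )
        if config.external_expr_path:
            ext = ExpressionMatrix.from_tsv(config.external_expr_path)
            labels, probs = transfer_labels(model, ext)
            with open(out / "external_labels.tsv", "w") as fh:
                fh.write(f"# {stamp}\nsample\tcluster\tprobability_C1\n")
                for s in ext.sample_ids:
                    fh.write(f"{s}\t{labels[s]}\t{probs[s]}\n")
            counts["external_samples"] = ext.n_samples
            if config.external_clinical_path:
                ext_surv = SurvivalTable.from_tsv(config.external_clinical_path).align(ext.sample_ids)
                if len(set(labels.values())) == 2:
                    cmp = compare_groups(ext_surv, labels)
                    counts["external_logrank_p"] = cmp["logrank_p"]
        return counts

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def run_demo(out_dir: str | Path, seed: int = 0, quick: bool = False, self_check: bool = True) -> dict:
    """Generate a synthetic dataset, run the full pipeline, and self-check.

    ``quick`` shrinks sample count and null repetitions to finish fast.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_dir = out / "data"
    data_dir.mkdir(exist_ok=True)

    # n stays at 300 in quick mode (hub orientation needs the sample size);
    # quick savings come from background genes, null reps, trees and LOOCV
    n_samples = 300
    n_background = 200 if quick else 1000
    gen_kwargs = dict(n_hubs=8, children_per_hub=10, subtype_effect=2.0,
                      hub_beta=0.45, edge_weight=0.7)
    truth = make_planted_truth(n_samples=n_samples, seed=seed, **gen_kwargs)
    mut = simulate_mutations(truth, seed=seed + 1)
    expr = simulate_expression(truth, seed=seed + 2, n_background=n_background, mutations=mut)
    surv = simulate_survival(expr, truth, censor_rate=0.3, seed=seed + 3)
    # held-out cohort from the same generator for transfer validation
    truth_ext = make_planted_truth(n_samples=max(n_samples // 2, 100), seed=seed + 10, **gen_kwargs)
    ext_expr = simulate_expression(truth_ext, seed=seed + 11, n_background=0)
    ext_expr = ExpressionMatrix(
        ext_expr.gene_ids, [f"X{s}" for s in ext_expr.sample_ids], ext_expr.values
    )
    ext_surv_raw = simulate_survival(
        simulate_expression(truth_ext, seed=seed + 11, n_background=0), truth_ext,
        censor_rate=0.3, seed=seed + 12,
    )
    ext_surv = SurvivalTable([f"X{s}" for s in ext_surv_raw.sample_ids], ext_surv_raw.time, ext_surv_raw.event)

    expr.to_tsv(data_dir / "expression.tsv")
    surv.to_tsv(data_dir / "clinical.tsv")
    mut.to_tsv(data_dir / "mutations.tsv")
    truth.to_json(data_dir / "ground_truth.json")
    truth.write_dag_tsv(data_dir / "true_dag.tsv")
    ext_expr.to_tsv(data_dir / "external_expression.tsv")
    ext_surv.to_tsv(data_dir / "external_clinical.tsv")

    config = PipelineConfig(
        expr_path=str(data_dir / "expression.tsv"),
        clinical_path=str(data_dir / "clinical.tsv"),
        mutations_path=str(data_dir / "mutations.tsv"),
        smg_list=list(truth.smg_ids),
        out_dir=str(out / "results"),
        standardize=True,
        pc_max_cond=3,
        null_reps=20 if quick else 100,
        null_consensus_reps=20 if quick else 50,
        consensus_reps=50 if quick else 100,
        n_trees=200 if quick else 500,
        predictor_alpha_grid=[1.0],
        predictor_lambda_grid=list(np.logspace(-3, -0.5, 8)),
        run_loocv=not quick,
        external_expr_path=str(data_dir / "external_expression.tsv"),
        external_clinical_path=str(data_dir / "external_clinical.tsv"),
        seed=seed,
    )
    manifest = run_pipeline(config)

    if self_check:
        checks = _demo_self_check(manifest, truth, out)
        manifest["self_check"] = checks
        _write_manifest(manifest, Path(config.out_dir))
        failed = [k for k, v in checks.items() if v is False]
        if failed:
            raise PipelineError("self_check", RuntimeError(f"failed checks: {failed}"))
    return manifest


def _demo_self_check(manifest: dict, truth, out: Path) -> dict:
    from sklearn.metrics import adjusted_rand_score

    results = Path(manifest["config"]["out_dir"])
    masters = [g for g in (results / "master_genes.txt").read_text().split() if g]
    recall = len(set(masters) & truth.master_genes) / len(truth.master_genes)

    labels = {}
    for line in (results / "subtype_labels.tsv").read_text().splitlines():
        if line.startswith(("#", "sample\t")):
            continue
        s, c = line.split("\t")
        labels[s] = c
    common = [s for s in truth.subtype_labels if s in labels]
    ari = adjusted_rand_score(
        [truth.subtype_labels[s] for s in common], [labels[s] for s in common]
    )

    sub_stage = manifest["stages"]["subtype"]
    observed = -np.log10(sub_stage["logrank_p"]) if sub_stage["logrank_p"] > 0 else np.inf
    null_vals = []
    for line in (results / "null_distribution.tsv").read_text().splitlines():
        if line.startswith(("#", "rep\t")):
            continue
        null_vals.append(float(line.split("\t")[1]))
    null95 = float(np.percentile(null_vals, 95))

    return {
        "hub_recall": recall,
        "hub_recall_ok": bool(recall >= 0.75),
        "subtype_ari": float(ari),
        "subtype_ari_ok": bool(ari >= 0.9),
        "observed_neglog10_p": float(observed),
        "null_95th_percentile": null95,
        "observed_above_null_ok": bool(observed > null95),
    }
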