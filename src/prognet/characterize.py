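"""Gene importance, pathway enrichment, and mutation/expression association."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import false_discovery_control

from .datatypes import ExpressionMatrix, MutationMatrix

__all__ = [
    "ImportanceRanking",
    "EnrichmentResult",
    "MutationAssociation",
    "rank_importance",
    "hypergeom_enrich",
    "mutation_expression_assoc",
    "smg_cluster_enrichment",
    "read_gmt",
]

log = logging.getLogger(__name__)


@dataclass
class ImportanceRanking:
    gene_id: str
    importance: float
    rank: int


def _oob_permutation_importance(forest, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mean out-of-bag accuracy decrease per feature, averaged over trees."""
    import inspect

    from sklearn.ensemble._forest import (  # sklearn private, pinned environment
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    n = X.shape[0]
    # the private helpers grew a sample_weight argument in newer sklearn
    if "sample_weight" in inspect.signature(_get_n_samples_bootstrap).parameters:
        n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)

        def unsampled(tree):
            return _generate_unsampled_indices(tree.random_state, n, n_boot, None)
    else:  # pragma: no cover - older sklearn
        n_boot = _get_n_samples_bootstrap(n, forest.max_samples)

        def unsampled(tree):
            return _generate_unsampled_indices(tree.random_state, n, n_boot)

    X32 = np.ascontiguousarray(X, dtype=np.float32)
    decreases = np.zeros(X.shape[1])
    counts = np.zeros(X.shape[1])
    for tree in forest.estimators_:
        oob = unsampled(tree)
        if len(oob) == 0:
            continue
        Xo = X32[oob]
        pred = tree.tree_.predict(Xo).reshape(len(oob), -1).argmax(axis=1)
        base = np.mean(pred == y[oob])
        for f in range(X.shape[1]):
            perm = rng.permutation(len(oob))
            Xp = Xo.copy()
            Xp[:, f] = Xo[perm, f]
            pred_p = tree.tree_.predict(Xp).reshape(len(oob), -1).argmax(axis=1)
            decreases[f] += base - np.mean(pred_p == y[oob])
            counts[f] += 1
    counts[counts == 0] = 1
    return decreases / counts


def rank_importance(
    expr_scaled: ExpressionMatrix,
    labels: dict[str, str] | list[str],
    n_trees: int = 500,
    seed: int = 0,
    method: str = "permutation",
) -> list[ImportanceRanking]:
    """Random-forest gene importance for predicting the subtype labels.

    ``method='permutation'`` (default) is out-of-bag permutation importance
    (mean accuracy decrease); ``method='impurity'`` uses Gini importances.
    Ties are broken lexicographically by gene id.
    """
    from sklearn.ensemble import RandomForestClassifier

    if isinstance(labels, dict):
        lab = np.array([labels[s] for s in expr_scaled.sample_ids])
    else:
        lab = np.asarray(labels)
    classes = np.unique(lab)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    counts = {c: int(np.sum(lab == c)) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError("need at least 2 samples per class")

    X = expr_scaled.values.T
    y = np.searchsorted(classes, lab)
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=False, n_jobs=1
    )
    forest.fit(X, y)

    if method == "impurity":
        imp = forest.feature_importances_
    elif method == "permutation":
        imp = _oob_permutation_importance(forest, X, y, np.random.default_rng(seed))
    else:
        raise ValueError(f"unknown importance method {method!r}")

    order = sorted(range(len(imp)), key=lambda i: (-imp[i], expr_scaled.gene_ids[i]))
    return [
        ImportanceRanking(expr_scaled.gene_ids[i], float(imp[i]), rank + 1)
        for rank, i in enumerate(order)
    ]


@dataclass
class EnrichmentResult:
    pathway_id: str
    overlap: int
    pathway_size: int
    universe_size: int
    draw_size: int
    p_value: float
    fdr: float


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def hypergeom_enrich(
    top_genes: set[str],
    pathways: dict[str, set[str]],
    universe: set[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of ``top_genes`` per pathway.

    Pathways are intersected with the universe first; BH FDR across pathways.
    """
    extra = set(top_genes) - set(universe)
    if extra:
        raise ValueError(f"top genes outside the universe: {sorted(extra)[:5]}")
    m = len(universe)
    n_draw = len(top_genes)
    rows = []
    for name in sorted(pathways):
        members = pathways[name] & universe
        if not members:
            log.warning("pathway %s has no genes in the universe; skipped", name)
            continue
        k = len(top_genes & members)
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n_draw))
        rows.append((name, k, len(members), p))
    if not rows:
        return []
    fdrs = false_discovery_control([r[3] for r in rows], method="bh")
    return [
        EnrichmentResult(name, k, size, m, n_draw, p, float(f))
        for (name, k, size, p), f in zip(rows, fdrs)
    ]


@dataclass
class MutationAssociation:
    smg_id: str
    gene_id: str
    fold_change: float
    p_value: float
    fdr: float
    significant: bool


def _linear_fold_change(mean_mut: float, mean_wild: float, scale: str) -> float:
    if scale == "log2":
        return float(2.0 ** (mean_mut - mean_wild))
    if scale == "ln":
        return float(np.exp(mean_mut - mean_wild))
    if scale == "linear":
        if mean_wild == 0:
            return float("inf") if mean_mut > 0 else 1.0
        return float(mean_mut / mean_wild)
    raise ValueError(f"unknown expression scale {scale!r}")


def mutation_expression_assoc(
    expr: ExpressionMatrix,
    mut: MutationMatrix,
    smg: str,
    test: str = "t",
    scale: str = "log2",
    fdr_threshold: float = 0.1,
) -> list[MutationAssociation]:
    """Differential expression between mutated and wild-type samples of one SMG.

    ``test`` is the unpaired two-sided t-test (default) or 'wilcoxon'
    (Mann-Whitney). Fold change is the linear-scale mean ratio given the
    declared input ``scale``. BH FDR across genes, significant at fdr < 0.1.
    """
    if smg not in mut.gene_ids:
        raise KeyError(f"SMG {smg!r} not in mutation matrix")
    carriers = set(mut.mutated_samples(smg))
    mask = np.array([s in carriers for s in expr.sample_ids])
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError(f"SMG {smg!r}: both mutated and wild-type groups must be nonempty")

    rows = []
    for gi, gene in enumerate(expr.gene_ids):
        a = expr.values[gi][mask]
        b = expr.values[gi][~mask]
        if len(a) < 2 or len(b) < 2:
            log.warning("gene %s skipped: group too small", gene)
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        elif test == "t":
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        elif test == "wilcoxon":
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        if not np.isfinite(p):
            p = 1.0
        fc = _linear_fold_change(float(a.mean()), float(b.mean()), scale)
        rows.append((gene, fc, p))
    if not rows:
        return []
    fdrs = false_discovery_control([r[2] for r in rows], method="bh")
    return [
        MutationAssociation(smg, gene, fc, p, float(f), bool(f < fdr_threshold))
        for (gene, fc, p), f in zip(rows, fdrs)
    ]


def smg_cluster_enrichment(
    mut: MutationMatrix,
    labels: dict[str, str] | list[str],
) -> pd.DataFrame:
    """Fisher's exact enrichment of each SMG's mutations in one cluster.

    Returns a frame with columns smg, odds_ratio (Haldane 0.5 correction on
    zero cells), p, fdr. The odds ratio is mutated-in-C1 vs mutated-in-C2.
    """
    if isinstance(labels, dict):
        lab = np.array([labels[s] for s in mut.sample_ids])
    else:
        lab = np.asarray(labels)
    clusters = sorted(set(lab.tolist()))
    if len(clusters) != 2:
        raise ValueError("need exactly two clusters")
    c1 = lab == clusters[0]
    rows = []
    for gi, smg in enumerate(mut.gene_ids):
        m = mut.values[gi].astype(bool)
        a = int(np.sum(m & c1))       # mutated in C1
        b = int(np.sum(m & ~c1))      # mutated in C2
        c = int(np.sum(~m & c1))
        d = int(np.sum(~m & ~c1))
        _stat, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            a_, b_, c_, d_ = a, b, c, d
        orr = (a_ * d_) / (b_ * c_)
        rows.append((smg, float(orr), float(p)))
    fdrs = false_discovery_control([r[2] for r in rows], method="bh")
    return pd.DataFrame(
        {
            "smg": [r[0] for r in rows],
            "odds_ratio": [r[1] for r in rows],
            "p": [r[2] for r in rows],
            "fdr": fdrs,
        }
    )


def importance_to_tsv(ranking: list[ImportanceRanking], path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene\timportance\trank\n")
        for r in ranking:
            fh.write(f"{r.gene_id}\t{r.importance}\t{r.rank}\n")


def enrichment_to_tsv(results: list[EnrichmentResult], path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("pathway\toverlap\tpathway_size\tuniverse_size\tdraw_size\tp\tfdr\n")
        for r in results:
            fh.write(
                f"{r.pathway_id}\t{r.overlap}\t{r.pathway_size}\t{r.universe_size}\t"
                f"{r.draw_size}\t{r.p_value}\t{r.fdr}\n"
            )


def associations_to_tsv(assocs: list[MutationAssociation], path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("smg\tgene\tfold_change\tp\tfdr\tsignificant\n")
        for r in assocs:
            fh.write(f"{r.smg_id}\t{r.gene_id}\t{r.fold_change}\t{r.p_value}\t{r.fdr}\t{int(r.significant)}\n")
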