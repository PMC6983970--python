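"""Consensus clustering of samples into expression subtypes.

Partitioning around medoids (PAM) with the deterministic BUILD + SWAP
procedure is run on subsampled cohorts; co-clustering frequencies form the
consensus matrix, whose hierarchical cut gives the final labels. C1 always
denotes the worse-prognosis cluster when survival data are supplied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix, SurvivalTable
from .screen import compare_groups, cox_univariate

__all__ = [
    "SubtypeResult",
    "NullDistribution",
    "zscore_genes",
    "pam",
    "consensus_cluster",
    "random_gene_null",
]

log = logging.getLogger(__name__)


def zscore_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene standardization to mean 0, population SD 1.

    Constant genes cannot be scaled and are dropped with a warning.
    """
    sd = expr.values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} constant genes: {dropped[:5]}...", stacklevel=2)
    vals = expr.values[keep]
    vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    return ExpressionMatrix([g for g, k in zip(expr.gene_ids, keep) if k], list(expr.sample_ids), vals)


def pam(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Classic PAM (BUILD + greedy SWAP) on a precomputed distance matrix.

    Fully deterministic given the distance matrix; returns integer labels
    0..k-1 indexed by medoid order.
    """
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not 1 <= k <= n:
        raise ValueError("k out of range")

    # BUILD: first medoid minimizes total distance, then greedy additions
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    def total_cost(meds: list[int]) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    cost = total_cost(medoids)
    for _ in range(max_iter):
        best_delta = 0.0
        best_swap = None
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            base = dist[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in range(n):
                if h in medoids:
                    continue
                new_cost = float(np.minimum(base, dist[:, h]).sum())
                delta = new_cost - cost
                if delta < best_delta - 1e-12:
                    best_delta = delta
                    best_swap = (mi, h, new_cost)
        if best_swap is None:
            break
        mi, h, cost = best_swap
        medoids[mi] = h
    medoids = sorted(medoids)
    return np.argmin(dist[:, medoids], axis=1)


@dataclass
class SubtypeResult:
    sample_ids: list[str]
    labels: dict[str, str]
    consensus: np.ndarray
    logrank_p: float
    cluster_sizes: tuple[int, ...]

    def labels_array(self) -> np.ndarray:
        return np.array([self.labels[s] for s in self.sample_ids])

    def write_labels(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("sample\tcluster\n")
            for s in self.sample_ids:
                fh.write(f"{s}\t{self.labels[s]}\n")

    def write_consensus(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df = pd.DataFrame(self.consensus, index=self.sample_ids, columns=self.sample_ids)
            df.index.name = "sample"
            df.to_csv(fh, sep="\t")


def _sample_distance(expr_scaled: ExpressionMatrix, metric: str) -> np.ndarray:
    if metric == "correlation":
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(expr_scaled.values.T)
        corr = np.nan_to_num(corr, nan=0.0)
        d = 1.0 - corr
    elif metric == "euclidean":
        x = expr_scaled.values.T
        sq = np.sum(x**2, axis=1)
        d = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * x @ x.T, 0.0))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def consensus_cluster(
    expr_scaled: ExpressionMatrix,
    k: int = 2,
    n_reps: int = 100,
    item_frac: float = 0.8,
    seed: int = 0,
    surv: SurvivalTable | None = None,
    metric: str = "correlation",
) -> SubtypeResult:
    """Subsampled-PAM consensus clustering into ``k`` groups.

    Each repetition subsamples ``item_frac`` of samples without replacement,
    clusters them by PAM on 1 - Pearson correlation between sample profiles,
    and the consensus entry (i, j) is co-cluster count / co-sampled count.
    Final labels come from an average-linkage cut of 1 - consensus. When a
    survival table is supplied, the worse-prognosis cluster is named C1.
    """
    n = expr_scaled.n_samples
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < 3 * k:
        raise ValueError("need at least 3k samples")
    rng = np.random.default_rng(seed)
    dist = _sample_distance(expr_scaled, metric)
    m = max(int(np.ceil(item_frac * n)), k)

    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(n_reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = dist[np.ix_(idx, idx)]
        lab = pam(sub, k)
        sampled[np.ix_(idx, idx)] += 1.0
        for c in range(k):
            members = idx[lab == c]
            together[np.ix_(members, members)] += 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    if np.any((sampled == 0) & ~np.eye(n, dtype=bool)):
        warnings.warn("some sample pairs were never co-sampled; consensus set to 0", stacklevel=2)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    link = linkage(squareform(1.0 - consensus, checks=False), method="average")
    raw = fcluster(link, t=k, criterion="maxclust")
    if len(set(raw)) < k:  # degenerate tree; fall back to PAM on full data
        raw = pam(dist, k) + 1

    label_names = _assign_cluster_names(raw, expr_scaled.sample_ids, surv)
    labels = {s: label_names[r] for s, r in zip(expr_scaled.sample_ids, raw)}
    logrank_p = float("nan")
    if surv is not None and k == 2:
        try:
            logrank_p = compare_groups(surv.align(expr_scaled.sample_ids), labels)["logrank_p"]
        except ValueError as exc:
            log.warning("log-rank comparison unavailable: %s", exc)
    sizes = tuple(int(np.sum(raw == c)) for c in sorted(set(raw)))
    return SubtypeResult(list(expr_scaled.sample_ids), labels, consensus, logrank_p, sizes)


def _assign_cluster_names(
    raw: np.ndarray, sample_ids: list[str], surv: SurvivalTable | None
) -> dict[int, str]:
    """Map raw cluster ids to C1/C2/... with C1 = worse prognosis."""
    ids = sorted(set(raw.tolist()))
    if surv is None or len(ids) != 2:
        return {c: f"C{i + 1}" for i, c in enumerate(ids)}
    aligned = surv.align(sample_ids)
    indicator = (raw == ids[0]).astype(float)
    coef, _se, _p, converged = cox_univariate(indicator, aligned.time, aligned.event)
    if not converged or coef == 0.0:
        means = [aligned.time[raw == c].mean() for c in ids]
        worse_first = means[0] <= means[1]
    else:
        worse_first = coef > 0
    if worse_first:
        return {ids[0]: "C1", ids[1]: "C2"}
    return {ids[0]: "C2", ids[1]: "C1"}


@dataclass
class NullDistribution:
    neglog10_p: np.ndarray
    n_reps: int
    genes_per_rep: int
    observed_neglog10_p: float

    def __post_init__(self) -> None:
        self.neglog10_p = np.asarray(self.neglog10_p, dtype=float)
        if self.neglog10_p.shape != (self.n_reps,):
            raise ValueError("null vector length must equal n_reps")

    def empirical_p(self) -> float:
        """(1 + #{null >= observed}) / (n_reps + 1), always in (0, 1]."""
        return float((1 + np.sum(self.neglog10_p >= self.observed_neglog10_p)) / (self.n_reps + 1))

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.neglog10_p, q))

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# observed_neglog10_p={self.observed_neglog10_p}\tgenes_per_rep={self.genes_per_rep}\n")
            fh.write("rep\tneglog10_p\n")
            for i, v in enumerate(self.neglog10_p):
                fh.write(f"{i}\t{v}\n")


def random_gene_null(
    expr_full: ExpressionMatrix,
    surv: SurvivalTable,
    n_genes: int,
    n_reps: int = 100,
    seed: int = 0,
    consensus_reps: int = 100,
    item_frac: float = 0.8,
    observed_neglog10_p: float = float("nan"),
) -> NullDistribution:
    """Null distribution of the subtype log-rank statistic over random genes.

    Per repetition, ``n_genes`` genes are drawn uniformly without replacement
    from ``expr_full`` (assumed already zero-filtered), z-scored and consensus
    clustered at k=2; -log10 of the two-group log-rank p is recorded.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if expr_full.n_genes < n_genes:
        raise ValueError("not enough genes to sample from")
    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2**63 - 1, size=2 * n_reps)
    vals = np.empty(n_reps)
    for rep in range(n_reps):
        pick_rng = np.random.default_rng(child_seeds[2 * rep])
        idx = pick_rng.choice(expr_full.n_genes, size=n_genes, replace=False)
        sub = ExpressionMatrix(
            [expr_full.gene_ids[i] for i in idx], list(expr_full.sample_ids), expr_full.values[idx]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaled = zscore_genes(sub)
        res = consensus_cluster(
            scaled,
            k=2,
            n_reps=consensus_reps,
            item_frac=item_frac,
            seed=int(child_seeds[2 * rep + 1]),
            surv=surv,
        )
        p = res.logrank_p
        vals[rep] = -np.log10(p) if np.isfinite(p) and p > 0 else 0.0
    return NullDistribution(vals, n_reps, n_genes, observed_neglog10_p)
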