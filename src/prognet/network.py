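"""Biweight midcorrelation, PC-algorithm CPDAG estimation and hub scoring.

The skeleton search is the order-independent ("stable") PC variant: at each
conditioning-set size the adjacency sets are frozen before edges are tested,
so edge removals within a level cannot influence one another. Conditional
independence is judged by Fisher-z tests on partial correlations derived
from the supplied correlation matrix; the CI test is pluggable so a
d-separation oracle can be substituted for exact-recovery checks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Hashable, Sequence

import numpy as np
from scipy.special import ndtr

from .datatypes import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "Cpdag",
    "DegreeSummary",
    "bicor_matrix",
    "bicor",
    "pc_estimate",
    "pc_from_ci_test",
    "summarize_degrees",
    "select_masters",
]

log = logging.getLogger(__name__)

CITest = Callable[[Hashable, Hashable, tuple], bool]  # True = independent


# ---------------------------------------------------------------------------
# biweight midcorrelation
# ---------------------------------------------------------------------------

def _bicor_transform(x: np.ndarray) -> np.ndarray:
    """Median-centered, bisquare-weighted deviations for one variable.

    Weight w_i = (1 - u_i^2)^2 for |u_i| < 1 with u_i = (x_i - med) / (9 MAD).
    Falls back to plain mean-centering (Pearson-style) when MAD is zero.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        v = x - np.mean(x)
    else:
        with np.errstate(over="ignore"):
            u = (x - med) / (9.0 * mad)
        uc = np.clip(u, -1.0, 1.0)  # weight is 0 outside |u| < 1 anyway
        w = (1.0 - uc**2) ** 2 * (np.abs(u) < 1.0)
        v = (x - med) * w
    # rescale to unit max-abs: correlation-invariant, avoids under/overflow
    peak = np.max(np.abs(v))
    return v / peak if peak > 0 else v


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two vectors."""
    a = _bicor_transform(np.asarray(x, float))
    b = _bicor_transform(np.asarray(y, float))
    na = np.sqrt(np.sum(a**2))
    nb = np.sqrt(np.sum(b**2))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


@dataclass
class CorrelationMatrix:
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square over gene_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(self.values) > 1.0 + 1e-10):
            raise ValueError("correlation entries must lie in [-1, 1]")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("correlation diagonal must be 1")


def bicor_matrix(expr: ExpressionMatrix) -> CorrelationMatrix:
    """All-pairs biweight midcorrelation of gene rows."""
    if expr.n_samples < 4:
        raise ValueError("need at least 4 samples for correlation estimation")
    transformed = np.empty_like(expr.values)
    zero_mad = 0
    for i in range(expr.n_genes):
        row = expr.values[i]
        if np.median(np.abs(row - np.median(row))) == 0.0:
            zero_mad += 1
        transformed[i] = _bicor_transform(row)
    if zero_mad:
        log.warning("%d genes had zero MAD; using mean-centered fallback", zero_mad)
    norms = np.sqrt(np.sum(transformed**2, axis=1))
    norms[norms == 0.0] = 1.0
    unit = transformed / norms[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return CorrelationMatrix(list(expr.gene_ids), corr)


# ---------------------------------------------------------------------------
# CPDAG container
# ---------------------------------------------------------------------------

@dataclass
class Cpdag:
    """Partially directed graph: directed edges (u, v) plus undirected pairs."""

    nodes: list
    directed_edges: set
    undirected_edges: set

    def __post_init__(self) -> None:
        self.directed_edges = {(u, v) for u, v in self.directed_edges}
        self.undirected_edges = {frozenset(e) for e in self.undirected_edges}
        for u, v in self.directed_edges:
            if u == v:
                raise ValueError("self loop in directed edges")
            if (v, u) in self.directed_edges:
                raise ValueError(f"2-cycle between {u} and {v}")
            if frozenset((u, v)) in self.undirected_edges:
                raise ValueError(f"edge {u}-{v} is both directed and undirected")
        for e in self.undirected_edges:
            if len(e) != 2:
                raise ValueError("undirected self loop")

    @property
    def skeleton(self) -> set:
        return {frozenset((u, v)) for u, v in self.directed_edges} | set(self.undirected_edges)

    def to_edge_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("source\ttarget\ttype\n")
            for u, v in sorted(self.directed_edges):
                fh.write(f"{u}\t{v}\tdirected\n")
            for e in sorted(tuple(sorted(e)) for e in self.undirected_edges):
                fh.write(f"{e[0]}\t{e[1]}\tundirected\n")

    @classmethod
    def from_edge_tsv(cls, path: str | Path, nodes: Sequence | None = None) -> "Cpdag":
        directed, undirected = set(), set()
        seen = set()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("source\t"):
                    continue
                u, v, kind = line.rstrip("\n").split("\t")
                seen.update((u, v))
                if kind == "directed":
                    directed.add((u, v))
                else:
                    undirected.add(frozenset((u, v)))
        return cls(list(nodes) if nodes is not None else sorted(seen), directed, undirected)


# ---------------------------------------------------------------------------
# PC algorithm
# ---------------------------------------------------------------------------

def _stable_skeleton(
    nodes: Sequence,
    ci_test: CITest,
    max_cond_size: int | None = None,
) -> tuple[dict, dict]:
    adj = {v: set(nodes) - {v} for v in nodes}
    sepset: dict[tuple, frozenset] = {}
    level = 0
    while True:
        if max_cond_size is not None and level > max_cond_size:
            break
        frozen = {v: frozenset(adj[v]) for v in nodes}
        if not any(len(frozen[v]) - 1 >= level for v in nodes):
            break
        for i in nodes:
            for j in sorted(frozen[i]):
                if j not in adj[i]:
                    continue
                candidates = sorted(frozen[i] - {j})
                if len(candidates) < level:
                    continue
                for cond in itertools.combinations(candidates, level):
                    if ci_test(i, j, cond):
                        adj[i].discard(j)
                        adj[j].discard(i)
                        sepset[(i, j)] = sepset[(j, i)] = frozenset(cond)
                        break
        level += 1
    return adj, sepset


def _orient_v_structures(nodes: Sequence, adj: dict, sepset: dict) -> tuple[set, set]:
    """Return (directed, undirected) after collider orientation.

    Conflicting orientations of the same edge from different v-structures are
    resolved by leaving the edge undirected.
    """
    votes: dict[frozenset, set] = {}
    for k in nodes:
        neighbours = sorted(adj[k])
        for i, j in itertools.combinations(neighbours, 2):
            if j in adj[i]:
                continue  # shielded
            sep = sepset.get((i, j))
            if sep is None or k in sep:
                continue
            votes.setdefault(frozenset((i, k)), set()).add((i, k))
            votes.setdefault(frozenset((j, k)), set()).add((j, k))
    directed = set()
    undirected = set()
    for i in nodes:
        for j in adj[i]:
            key = frozenset((i, j))
            if key in undirected or key in votes and len(votes[key]) == 2:
                undirected.add(key)
                continue
            if key in votes:
                directed.add(next(iter(votes[key])))
            else:
                undirected.add(key)
    # drop undirected duplicates of directed edges (conflict resolution above)
    undirected = {e for e in undirected if tuple(e) not in directed and tuple(reversed(tuple(e))) not in directed}
    directed = {e for e in directed if frozenset(e) not in undirected}
    return directed, undirected


def _apply_meek_rules(nodes: Sequence, directed: set, undirected: set) -> tuple[set, set]:
    """Meek orientation rules R1-R4 applied to a fixpoint."""
    directed = set(directed)
    undirected = set(undirected)

    def adjacent(a, b):
        return (a, b) in directed or (b, a) in directed or frozenset((a, b)) in undirected

    def orient(a, b) -> bool:
        e = frozenset((a, b))
        if e in undirected and (b, a) not in directed:
            undirected.discard(e)
            directed.add((a, b))
            return True
        return False

    changed = True
    while changed:
        changed = False
        for e in list(undirected):
            a, b = tuple(e)
            for x, y in ((a, b), (b, a)):
                # R1: z -> x, x - y, z and y non-adjacent  =>  x -> y
                if any((z, x) in directed and not adjacent(z, y) for z in nodes if z not in (x, y)):
                    changed |= orient(x, y)
                    break
                # R2: x -> z -> y and x - y  =>  x -> y
                if any((x, z) in directed and (z, y) in directed for z in nodes if z not in (x, y)):
                    changed |= orient(x, y)
                    break
                # R3: x - z1, x - z2, z1 -> y, z2 -> y, z1/z2 non-adjacent  =>  x -> y
                spouses = [
                    z for z in nodes
                    if z not in (x, y) and frozenset((x, z)) in undirected and (z, y) in directed
                ]
                if any(
                    not adjacent(z1, z2)
                    for z1, z2 in itertools.combinations(spouses, 2)
                ):
                    changed |= orient(x, y)
                    break
                # R4: x adjacent d, d -> c, c -> y, d/y non-adjacent  =>  x -> y
                if any(
                    (d, c) in directed and (c, y) in directed
                    and adjacent(x, d) and not adjacent(d, y)
                    for d, c in itertools.permutations([z for z in nodes if z not in (x, y)], 2)
                ):
                    changed |= orient(x, y)
                    break
            if changed:
                break
    return directed, undirected


def pc_from_ci_test(
    nodes: Sequence,
    ci_test: CITest,
    max_cond_size: int | None = None,
) -> Cpdag:
    """Run stable-PC with an arbitrary conditional-independence test."""
    adj, sepset = _stable_skeleton(nodes, ci_test, max_cond_size)
    directed, undirected = _orient_v_structures(nodes, adj, sepset)
    directed, undirected = _apply_meek_rules(nodes, directed, undirected)
    return Cpdag(list(nodes), directed, undirected)


def _nearest_psd(corr: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= eps:
        return corr
    log.warning("correlation matrix not positive definite; clipping eigenvalues")
    vals = np.clip(vals, eps, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


def fisher_z_ci_test(corr: np.ndarray, n_samples: int, alpha: float) -> CITest:
    """Fisher-z partial-correlation CI test over a correlation matrix.

    Partial correlations come from inverting the submatrix over the pair plus
    conditioning set; a singular submatrix is treated as a non-significant
    (independent) outcome with a log message.
    """
    def test(i: int, j: int, cond: tuple) -> bool:
        idx = [i, j, *cond]
        sub = corr[np.ix_(idx, idx)]
        try:
            prec = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            log.warning("singular conditioning submatrix for (%s, %s | %s)", i, j, cond)
            return True
        denom = prec[0, 0] * prec[1, 1]
        if denom <= 0:
            log.warning("non-PD conditioning submatrix for (%s, %s | %s)", i, j, cond)
            return True
        r = -prec[0, 1] / np.sqrt(denom)
        r = float(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
        dof = n_samples - len(cond) - 3
        if dof <= 0:
            return True
        stat = np.sqrt(dof) * abs(np.arctanh(r))
        p = 2.0 * (1.0 - ndtr(stat))
        return p > alpha

    return test


def pc_estimate(
    corr: CorrelationMatrix,
    n_samples: int,
    alpha: float = 0.01,
    max_cond_size: int | None = None,
) -> Cpdag:
    """Estimate a CPDAG from a correlation matrix by stable-PC + Meek rules."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if max_cond_size is not None and n_samples <= max_cond_size + 3:
        raise ValueError("n_samples must exceed max_cond_size + 3")
    mat = _nearest_psd(corr.values)
    test = fisher_z_ci_test(mat, n_samples, alpha)
    idx_cpdag = pc_from_ci_test(list(range(len(corr.gene_ids))), test, max_cond_size)
    names = corr.gene_ids
    return Cpdag(
        list(names),
        {(names[u], names[v]) for u, v in idx_cpdag.directed_edges},
        {frozenset((names[u], names[v])) for e in idx_cpdag.undirected_edges for u, v in [tuple(e)]},
    )


# ---------------------------------------------------------------------------
# degree summaries and master selection
# ---------------------------------------------------------------------------

@dataclass
class DegreeSummary:
    gene_id: str
    out_degree: int
    in_degree: int
    summarized_degree: int
    is_master: bool


def summarize_degrees(g: Cpdag, hub_threshold: int = 5) -> list[DegreeSummary]:
    """Out minus in degree over directed edges only; undirected edges count 0."""
    out_deg = {v: 0 for v in g.nodes}
    in_deg = {v: 0 for v in g.nodes}
    for u, v in g.directed_edges:
        out_deg[u] += 1
        in_deg[v] += 1
    summaries = []
    for v in g.nodes:
        sd = out_deg[v] - in_deg[v]
        summaries.append(
            DegreeSummary(str(v), out_deg[v], in_deg[v], sd, abs(sd) > hub_threshold)
        )
    return summaries


def select_masters(summaries: list[DegreeSummary]) -> list[str]:
    """Master genes ordered by |summarized degree| descending, ties by id."""
    if not summaries:
        raise ValueError("summaries must be nonempty")
    masters = [s for s in summaries if s.is_master]
    masters.sort(key=lambda s: (-abs(s.summarized_degree), s.gene_id))
    return [s.gene_id for s in masters]


def degrees_to_tsv(summaries: list[DegreeSummary], path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene\tout_degree\tin_degree\tsummarized_degree\tis_master\n")
        for s in summaries:
            fh.write(f"{s.gene_id}\t{s.out_degree}\t{s.in_degree}\t{s.summarized_degree}\t{int(s.is_master)}\n")
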