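"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration / closed form) and shares
no code with the implementations it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# graphs: d-separation, Markov equivalence, CPDAG by enumeration
# ---------------------------------------------------------------------------

def dseparated(nodes, edges, x, y, cond) -> bool:
    """d-separation via the moralized ancestral graph criterion."""
    cond = set(cond)
    parents = {v: set() for v in nodes}
    for u, v in edges:
        parents[v].add(u)

    # ancestral set of {x, y} | cond
    anc = set()
    frontier = {x, y} | cond
    while frontier:
        v = frontier.pop()
        if v in anc:
            continue
        anc.add(v)
        frontier |= parents[v] - anc

    # moralize: connect co-parents, drop directions
    adj = {v: set() for v in anc}
    for u, v in edges:
        if u in anc and v in anc:
            adj[u].add(v)
            adj[v].add(u)
    for v in anc:
        ps = [p for p in parents[v] if p in anc]
        for a, b in itertools.combinations(ps, 2):
            adj[a].add(b)
            adj[b].add(a)

    # connectivity avoiding cond
    if x in cond or y in cond:
        return True
    seen = {x}
    stack = [x]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w == y:
                return False
            if w not in seen and w not in cond:
                seen.add(w)
                stack.append(w)
    return True


def _vstructures(nodes, edges):
    edges = set(edges)
    adj = {v: set() for v in nodes}
    parents = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
        parents[v].add(u)
    vs = set()
    for k in nodes:
        for a, b in itertools.combinations(sorted(parents[k]), 2):
            if b not in adj[a]:
                vs.add((a, b, k))
    return vs


def _is_acyclic(nodes, edges) -> bool:
    out = {v: set() for v in nodes}
    for u, v in edges:
        out[u].add(v)
    indeg = {v: 0 for v in nodes}
    for u, v in edges:
        indeg[v] += 1
    queue = [v for v in nodes if indeg[v] == 0]
    seen = 0
    while queue:
        v = queue.pop()
        seen += 1
        for w in out[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    return seen == len(nodes)


def true_cpdag(nodes, edges):
    """CPDAG of a DAG by enumerating its Markov-equivalence class.

    Every orientation of the skeleton that is acyclic and reproduces the
    DAG's v-structures is a class member; an edge is directed in the CPDAG
    iff it points the same way in every member.
    """
    nodes = list(nodes)
    edges = list(edges)
    skeleton = sorted({tuple(sorted(e)) for e in edges})
    target_vs = _vstructures(nodes, edges)
    members = []
    for bits in itertools.product([0, 1], repeat=len(skeleton)):
        candidate = [
            (a, b) if bit == 0 else (b, a)
            for (a, b), bit in zip(skeleton, bits)
        ]
        if _is_acyclic(nodes, candidate) and _vstructures(nodes, candidate) == target_vs:
            members.append(set(candidate))
    assert members, "equivalence class enumeration found no member"
    # an edge is "directed" only if no member flips it
    final_directed = set()
    for a, b in skeleton:
        orientations = {(a, b) in m for m in members}
        if all(orientations):
            final_directed.add((a, b))
        elif not any(orientations):
            final_directed.add((b, a))
    final_undirected = {
        frozenset((a, b)) for a, b in skeleton
        if (a, b) not in final_directed and (b, a) not in final_directed
    }
    return final_directed, final_undirected


def all_dags(n_nodes: int):
    """Yield every labeled DAG on nodes 0..n-1 as a tuple of edges."""
    nodes = list(range(n_nodes))
    pairs = list(itertools.combinations(nodes, 2))
    for states in itertools.product([0, 1, 2], repeat=len(pairs)):
        edges = []
        for (a, b), s in zip(pairs, states):
            if s == 1:
                edges.append((a, b))
            elif s == 2:
                edges.append((b, a))
        if _is_acyclic(nodes, edges):
            yield tuple(edges)


def random_dag(n_nodes: int, edge_prob: float, rng: np.random.Generator):
    """Random DAG: random topological order, independent edges."""
    order = rng.permutation(n_nodes)
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((int(order[i]), int(order[j])))
    return tuple(edges)


# ---------------------------------------------------------------------------
# bicor reference
# ---------------------------------------------------------------------------

def bicor_reference(x, y) -> float:
    """Direct transcription of the biweight-midcorrelation formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return v - np.mean(v)
        u = (v - med) / (9 * mad)
        ind = (np.abs(u) < 1).astype(float)
        return (v - med) * (1 - u**2) ** 2 * ind

    a = weights(x)
    b = weights(y)
    num = np.sum(a * b)
    den = np.sqrt(np.sum(a**2)) * np.sqrt(np.sum(b**2))
    return num / den if den > 0 else 0.0


# ---------------------------------------------------------------------------
# exact tests by enumeration
# ---------------------------------------------------------------------------

def hypergeom_upper_tail(k: int, m: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(universe m, successes K, draws n)."""
    total = comb(m, n)
    return sum(comb(K, i) * comb(m - K, n - i) for i in range(k, min(K, n) + 1)) / total


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    nn = r1 + r2

    def table_p(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(nn, c1)

    p_obs = table_p(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(table_p(x) for x in range(lo, hi + 1) if table_p(x) <= p_obs * (1 + 1e-9))
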