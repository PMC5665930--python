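"""Independent brute-force oracles used by the unit and acceptance tests.

Nothing here may call into the package's own implementations: betweenness
is computed by exhaustive simple-path enumeration, network edges by direct
pairwise set intersection, and q-values via an independent
Benjamini-Hochberg implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_betweenness(nodes, edges) -> dict:
    """Normalized directed betweenness by enumerating every simple path.

    For each ordered pair (s, t) all simple paths are enumerated by DFS;
    the shortest ones share one unit of credit equally among their
    intermediate nodes. Raw counts are normalized by (n-1)(n-2).
    """
    nodes = list(nodes)
    adj: dict = {u: [] for u in nodes}
    for u, v in edges:
        adj[u].append(v)
    raw = dict.fromkeys(nodes, 0.0)

    def all_paths(s, t):
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                yield path
                continue
            for nxt in adj[node]:
                if nxt not in path:
                    stack.append((nxt, path + [nxt]))

    for s, t in itertools.permutations(nodes, 2):
        paths = list(all_paths(s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for p in sp:
            for mid in p[1:-1]:
                raw[mid] += 1.0 / len(sp)
    n = len(nodes)
    scale = (n - 1) * (n - 2)
    if scale <= 0:
        return {u: 0.0 for u in nodes}
    return {u: raw[u] / scale for u in nodes}


def brute_force_edges(annotation: dict, blacklist=frozenset()) -> set:
    """Edge set by direct pairwise product/substrate intersection."""
    black = set(blacklist)
    out = set()
    for u, (_, prods_u) in annotation.items():
        for v, (subs_v, _) in annotation.items():
            if u != v and (set(prods_u) & set(subs_v)) - black:
                out.add((u, v))
    return out


def bh_qvalues(pvalues) -> np.ndarray:
    """Plain Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = adj
    return out


def random_digraph(rng: np.random.Generator, max_nodes: int = 8):
    """A random directed graph as (nodes, edges) with 2..max_nodes nodes."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    p = rng.uniform(0.1, 0.6)
    edges = [
        (u, v)
        for u, v in itertools.permutations(nodes, 2)
        if rng.random() < p
    ]
    return nodes, edges
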