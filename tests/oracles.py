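"""Independent brute-force oracles used by the test suite.

Each oracle deliberately uses a different algorithm from the library
path it checks (path enumeration instead of Brandes accumulation,
dense linear solves instead of power iteration, explicit step-up
instead of a q-value transform) so that agreement is evidence, not
tautology.
"""

from __future__ import annotations

import itertools
from collections import deque

import networkx as nx
import numpy as np


def betweenness_by_path_enumeration(graph: nx.Graph) -> dict:
    """Normalized betweenness by enumerating every shortest path."""
    nodes = list(graph)
    n = len(nodes)
    bet = dict.fromkeys(nodes, 0.0)
    if n < 3:
        return bet
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(graph, s, t):
            continue
        paths = list(nx.all_shortest_paths(graph, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            interior = sum(1 for p in paths if v in p[1:-1])
            bet[v] += interior / len(paths)
    scale = 2.0 / ((n - 1) * (n - 2))
    return {v: b * scale for v, b in bet.items()}


def closeness_wf_by_hand(graph: nx.Graph) -> dict:
    """Wasserman-Faust closeness from raw BFS distance dictionaries."""
    n = len(graph)
    out = {}
    for v in graph:
        dists = bfs_distances(graph, v)
        r = len(dists)  # includes v itself at distance 0
        total = sum(dists.values())
        if r <= 1 or total == 0:
            out[v] = 0.0
        else:
            out[v] = ((r - 1) / total) * ((r - 1) / (n - 1))
    return out


def bfs_distances(graph: nx.Graph, source) -> dict:
    """Hand-rolled BFS distance map (independent of networkx paths)."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in graph[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def dominant_eigenvector(graph: nx.Graph, nodes: list) -> np.ndarray:
    """Unit-L2 Perron vector of A @ A.T by dense eigendecomposition."""
    a = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    vals, vecs = np.linalg.eigh(a @ a.T)
    v = vecs[:, np.argmax(vals)]
    v = np.abs(v)
    return v / np.linalg.norm(v)


def rank_by_linear_scan(cent, k: int, exclude=()) -> list:
    """Re-rank candidates with repeated linear scans (selection sort)."""
    excl = {g.upper() for g in exclude}
    pool = [g for g in cent.index if g.upper() not in excl]

    def norm(col):
        vals = cent.loc[pool, col]
        lo, hi = float(vals.min()), float(vals.max())
        if hi == lo:
            return {g: 0.0 for g in pool}
        return {g: (float(vals[g]) - lo) / (hi - lo) for g in pool}

    nb, nc = norm("betweenness"), norm("closeness")
    score = {g: (nb[g] + nc[g]) / 2.0 for g in pool}
    picked = []
    remaining = list(pool)
    for _ in range(k):
        best = None
        for g in remaining:
            if best is None:
                best = g
                continue
            key_g = (-score[g], -int(cent.at[g, "degree"]), g)
            key_b = (-score[best], -int(cent.at[best, "degree"]), best)
            if key_g < key_b:
                best = g
        picked.append(best)
        remaining.remove(best)
    return picked


def bh_step_up_rejections(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Classic Benjamini-Hochberg step-up decision set (boolean mask)."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    sorted_p = pvals[order]
    thresholds = alpha * (np.arange(1, m + 1)) / m
    below = np.nonzero(sorted_p <= thresholds)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        k = below.max()
        reject[order[: k + 1]] = True
    return reject


def rwr_dense_solve(matrix, restart: float, p0: np.ndarray) -> np.ndarray:
    """Stationary RWR by direct linear solve (I - (1-r)W) p = r p0."""
    w = np.asarray(matrix.todense()) if hasattr(matrix, "todense") else np.asarray(matrix)
    n = w.shape[0]
    return np.linalg.solve(np.eye(n) - (1.0 - restart) * w, restart * p0)
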