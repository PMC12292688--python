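"""Independent brute-force oracles for centrality measures.

Everything here is deliberately naive and self-contained (hand-rolled BFS,
exhaustive geodesic enumeration, subset-based clique search) so it shares
no code path with the implementations it checks.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations


def adjacency_sets(nodes, edges):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def all_geodesics(adj, source, target):
    """Every shortest path from source to target, by distance-increasing DFS."""
    dist = bfs_distances(adj, source)
    if target not in dist:
        return []
    paths = []

    def extend(path):
        v = path[-1]
        if v == target:
            paths.append(list(path))
            return
        for u in adj[v]:
            if dist.get(u) == dist[v] + 1 and dist[u] <= dist[target]:
                path.append(u)
                extend(path)
                path.pop()

    extend([source])
    return paths


def betweenness_oracle(nodes, edges, normalized=False):
    """Σ over unordered pairs {s,t} of the fraction of geodesics through v."""
    adj = adjacency_sets(nodes, edges)
    nodes = list(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_geodesics(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    if normalized:
        n = len(nodes)
        denom = (n - 1) * (n - 2) / 2
        if denom > 0:
            score = {v: x / denom for v, x in score.items()}
    return score


def closeness_oracle(nodes, edges):
    """(k−1)/Σd within each node's connected component; singletons → 0."""
    adj = adjacency_sets(nodes, edges)
    out = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        total = sum(d for u, d in dist.items() if u != v)
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def lac_oracle(nodes, edges):
    """Average degree of v's neighbors inside the neighbor-induced subgraph."""
    adj = adjacency_sets(nodes, edges)
    out = {}
    for v in nodes:
        nbrs = adj[v]
        if not nbrs:
            out[v] = 0.0
            continue
        induced_edges = sum(1 for a, b in combinations(sorted(nbrs), 2) if b in adj[a])
        out[v] = 2 * induced_edges / len(nbrs)
    return out


def maximal_cliques_oracle(nodes, edges):
    """All maximal cliques by testing every subset (exponential; tiny n only)."""
    adj = adjacency_sets(nodes, edges)
    nodes = sorted(nodes)

    def is_clique(subset):
        return all(b in adj[a] for a, b in combinations(subset, 2))

    cliques = [
        set(subset)
        for r in range(1, len(nodes) + 1)
        for subset in combinations(nodes, r)
        if is_clique(subset)
    ]
    return [c for c in cliques if not any(c < d for d in cliques)]


def mcc_oracle(nodes, edges):
    out = {v: 0 for v in nodes}
    for clique in maximal_cliques_oracle(nodes, edges):
        if len(clique) == 1:
            continue
        weight = math.factorial(len(clique) - 1)
        for v in clique:
            out[v] += weight
    return out
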