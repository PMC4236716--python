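"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — dense linear algebra, exhaustive
summation, explicit path enumeration — and shares no code path with the
implementations under test.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


def dense_evc(graph) -> dict:
    """Principal adjacency eigenvector via a dense symmetric eigensolver."""
    nodes = sorted(graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v in graph.edges():
        A[index[u], index[v]] = A[index[v], index[u]] = 1.0
    w, V = np.linalg.eigh(A)
    vec = np.abs(V[:, np.argmax(w)])
    vec /= np.linalg.norm(vec)
    return dict(zip(nodes, vec))


def exhaustive_hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by exact summation of the hypergeometric pmf."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(n, K) + 1):
        if n - i > N - K:
            continue
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def stepup_bh(p_values) -> list:
    """Benjamini–Hochberg step-up adjustment, written out longhand."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p_values[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def brute_topology(graph) -> dict:
    """Diameter, mean shortest path, mean clustering, betweenness — all naive."""
    nodes = sorted(graph.nodes())
    adj = {v: sorted(graph[v]) for v in nodes}
    n = len(nodes)

    all_dist = {v: bfs_distances(adj, v) for v in nodes}
    pair_d = [all_dist[u][v] for u, v in itertools.combinations(nodes, 2)]
    diameter = max(pair_d)
    aspl = sum(pair_d) / len(pair_d)

    clustering = {}
    for v in nodes:
        nbrs = adj[v]
        d = len(nbrs)
        if d < 2:
            clustering[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if b in graph[a]
        )
        clustering[v] = 2.0 * links / (d * (d - 1))

    # betweenness by explicit enumeration of all shortest paths per pair
    between = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        target_d = all_dist[s][t]
        paths: list[list] = []
        stack = [[s]]
        while stack:
            path = stack.pop()
            u = path[-1]
            if u == t:
                paths.append(path)
                continue
            for v in adj[u]:
                if all_dist[s][v] == len(path) and all_dist[v][t] == target_d - len(path):
                    stack.append(path + [v])
        for path in paths:
            for interior in path[1:-1]:
                between[interior] += 1.0 / len(paths)
    scale = (n - 1) * (n - 2) / 2.0
    between = {v: b / scale for v, b in between.items()}

    return {
        "diameter": diameter,
        "avg_shortest_path": aspl,
        "clustering": clustering,
        "betweenness": between,
    }


def brute_kcore_weight(graph, v, degree_threshold: int = 2) -> float:
    """Vertex weight via hand-rolled k-core peeling of the closed neighborhood."""
    if len(graph[v]) < degree_threshold:
        return 0.0
    nodes = set(graph[v]) | {v}
    edges = {
        (a, b)
        for a, b in itertools.combinations(sorted(nodes), 2)
        if graph.has_edge(a, b)
    }

    def peel(k):
        keep = set(nodes)
        while True:
            deg = {u: 0 for u in keep}
            for a, b in edges:
                if a in keep and b in keep:
                    deg[a] += 1
                    deg[b] += 1
            drop = {u for u in keep if deg[u] < k}
            if not drop:
                return keep
            keep -= drop

    k_max = 0
    core = nodes
    for k in range(1, len(nodes)):
        remaining = peel(k)
        if remaining:
            k_max, core = k, remaining
        else:
            break
    if k_max == 0:
        return 0.0
    m = sum(1 for a, b in edges if a in core and b in core)
    nn = len(core)
    return k_max * (2.0 * m / (nn * (nn - 1)))


def densest_subsets(graph, top: int = 2):
    """Highest density*size connected vertex subsets by exhaustive enumeration."""
    nodes = sorted(graph.nodes())
    best = []
    for r in range(2, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sub = graph.subgraph(subset)
            if not _connected(sub):
                continue
            score = 2.0 * sub.number_of_edges() / (r * (r - 1)) * r
            best.append((score, frozenset(subset)))
    best.sort(key=lambda x: (-x[0], sorted(x[1])))
    return best[:top]


def _connected(sub) -> bool:
    nodes = list(sub.nodes())
    seen = {nodes[0]}
    queue = deque([nodes[0]])
    while queue:
        u = queue.popleft()
        for v in sub[u]:
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return len(seen) == len(nodes)


def independent_tuning_test(observed: float, samples, alpha: float):
    """One-sample two-tailed t-test written from the formula."""
    from scipy.stats import t as t_dist

    arr = np.asarray(samples, dtype=float)
    R = arr.size
    mean = arr.mean()
    sd = arr.std(ddof=1)
    if sd == 0.0:
        return (mean != observed), (0.0 if mean != observed else 1.0)
    t_stat = (mean - observed) / (sd / math.sqrt(R))
    p = 2.0 * float(t_dist.sf(abs(t_stat), R - 1))
    return p < alpha, p
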