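"""MCODE-style dense-module detection.

Vertex weighting scores each vertex by the density of the highest k-core of
its closed neighborhood times that core's k (zero below the degree
threshold).  Module prediction greedily expands from the highest-weight
unvisited seed: a neighbor joins when

* its weight exceeds ``(1 - node_score_threshold)`` times the seed weight
  (strict inequality), and
* adding it does not decrease the running module score density x size —
  equivalently, it must bring at least ``E/(n-1)`` edges into the current
  n-member, E-edge module.

The second (density-preservation) gate is this package's dialect choice: the
published descriptions of the algorithm are ambiguous about how expansion is
bounded, and a pure seed-weight gate freely crosses single-edge bridges
between equally dense regions, fusing clearly distinct modules.  With both
gates, two cliques joined by one bridge edge are reported as two modules.

Post-processing follows the published parameterization: haircut retains each
module's 2-core (iterated removal of degree-1 members); fluff is accepted as
a flag but not implemented (it was disabled in the analysis this package
reproduces); modules whose member subgraph lacks a k-core at the K-core
threshold are discarded.  All tie-breaks are lexicographic on node id, so the
output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


@dataclass(frozen=True)
class McodeParams:
    degree_threshold: int = 2
    node_score_threshold: float = 0.2
    kcore_threshold: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    include_loops_in_scoring: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.node_score_threshold <= 1.0):
            raise ValueError("node_score_threshold must lie in [0, 1]")
        if self.fluff:
            raise NotImplementedError("fluff post-processing is not implemented")
        if self.include_loops_in_scoring:
            raise NotImplementedError("loop-aware scoring is not implemented")


@dataclass(frozen=True)
class Module:
    members: frozenset
    seed_node: str
    score: float
    rank: int = 0

    @property
    def size(self) -> int:
        return len(self.members)


def _density(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def vertex_weight(network: nx.Graph, v, params: McodeParams = McodeParams()) -> float:
    """k x density of the highest k-core of v's closed neighborhood.

    Zero when deg(v) is below the degree threshold (such vertices never seed
    or strengthen a module).
    """
    if network.degree(v) < params.degree_threshold:
        return 0.0
    closed = set(network[v]) | {v}
    sub = network.subgraph(closed)
    core_numbers = nx.core_number(sub)
    k_max = max(core_numbers.values())
    if k_max == 0:
        return 0.0
    core_nodes = [u for u, c in core_numbers.items() if c >= k_max]
    core_sub = sub.subgraph(core_nodes)
    return k_max * _density(core_sub.number_of_nodes(), core_sub.number_of_edges())


def _expand(network, seed, weights, visited, params):
    """Greedy BFS expansion from a seed; returns the raw member set."""
    cutoff = (1.0 - params.node_score_threshold) * weights[seed]
    members = {seed}
    n_edges = 0
    frontier = [seed]
    depth = 0
    while frontier and depth < params.max_depth:
        next_frontier = []
        for u in sorted(frontier):
            for nb in sorted(network[u]):
                if nb in members or nb in visited:
                    continue
                if not weights[nb] > cutoff:
                    continue
                d_in = sum(1 for x in network[nb] if x in members)
                # density-preservation gate: new score >= current score
                if len(members) > 1 and d_in * (len(members) - 1) < n_edges:
                    continue
                members.add(nb)
                n_edges += d_in
                next_frontier.append(nb)
        frontier = next_frontier
        depth += 1
    return members


def _haircut(network: nx.Graph, members: set) -> set:
    """Iterated removal of degree-1 members, i.e. the module's 2-core."""
    sub = network.subgraph(members)
    return set(nx.k_core(sub, 2).nodes())


def find_modules(network: nx.Graph, params: McodeParams = McodeParams()) -> list[Module]:
    """Detect dense modules; disjoint member sets, ranked by score.

    Rank order: score desc, then size desc, then lexicographically smallest
    member.  A graph with no qualifying seed yields an empty list.
    """
    weights = {v: vertex_weight(network, v, params) for v in network.nodes()}
    seeds = sorted(weights, key=lambda v: (-weights[v], v))
    visited: set = set()
    raw_modules = []
    for seed in seeds:
        if seed in visited or weights[seed] <= 0.0:
            continue
        members = _expand(network, seed, weights, visited, params)
        if params.haircut:
            members = _haircut(network, members)
        if len(members) < 2:
            continue
        sub = network.subgraph(members)
        if not nx.core_number(sub) or max(nx.core_number(sub).values()) < params.kcore_threshold:
            continue
        score = _density(sub.number_of_nodes(), sub.number_of_edges()) * len(members)
        raw_modules.append((frozenset(members), seed, score))
        visited |= members  # haircut-trimmed vertices stay available
    raw_modules.sort(key=lambda m: (-m[2], -len(m[0]), min(m[0])))
    return [
        Module(members=m, seed_node=s, score=sc, rank=i + 1)
        for i, (m, s, sc) in enumerate(raw_modules)
    ]
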