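"""Descriptive network topology and the hierarchical-modularity exponent.

``summarize`` computes the standard analyzer panel (degrees, betweenness,
diameter, characteristic path length, clustering).  ``fit_clustering_power_law``
fits C(k) ~ k^-w, the mean local clustering coefficient as a function of
degree; a clearly positive w is the signature of hierarchical modularity in
scale-free networks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    diameter: int
    avg_shortest_path: float
    avg_clustering: float
    degree_distribution: dict = field(repr=False)
    betweenness: dict = field(repr=False)
    power_law_w: float | None = None
    power_law_r2: float | None = None


def summarize(network: nx.Graph, fit_ck: bool = True) -> TopologySummary:
    """Topology panel of a connected simple graph.

    Shortest-path metrics use breadth-first search from every source;
    betweenness is normalized by (n-1)(n-2)/2; local clustering is
    2*T(v)/(deg(v)(deg(v)-1)) with 0 for degree < 2.  Disconnected input is
    an error — summarize the largest component instead.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(network):
        raise ValueError(
            "network is disconnected; extract the largest connected component first"
        )
    n = network.number_of_nodes()
    if n == 1:
        diameter, aspl = 0, 0.0
    else:
        diameter = nx.diameter(network)
        aspl = nx.average_shortest_path_length(network)
    clustering = nx.clustering(network)
    degree_distribution = dict(sorted(Counter(d for _, d in network.degree()).items()))
    betweenness = nx.betweenness_centrality(network, normalized=True)
    w = r2 = None
    if fit_ck:
        try:
            w, r2 = fit_clustering_power_law(network)
        except ValueError:
            pass  # too few usable degree bins; exponent left unset
    return TopologySummary(
        n_nodes=n,
        n_edges=network.number_of_edges(),
        diameter=diameter,
        avg_shortest_path=aspl,
        avg_clustering=float(np.mean(list(clustering.values()))),
        degree_distribution=degree_distribution,
        betweenness=betweenness,
        power_law_w=w,
        power_law_r2=r2,
    )


def clustering_by_degree(network: nx.Graph) -> dict[int, float]:
    """C(k): mean local clustering coefficient over nodes of degree k."""
    clustering = nx.clustering(network)
    by_degree: dict[int, list[float]] = {}
    for node, deg in network.degree():
        by_degree.setdefault(deg, []).append(clustering[node])
    return {k: float(np.mean(v)) for k, v in sorted(by_degree.items())}


def fit_power_law(k_values, c_values) -> tuple[float, float]:
    """Fit C(k) = k^-w by OLS of log10 C on log10 k; returns (w, r^2)."""
    k = np.asarray(k_values, dtype=float)
    c = np.asarray(c_values, dtype=float)
    if k.size < 3:
        raise ValueError("need >= 3 points for a power-law fit")
    if np.any(k <= 0) or np.any(c <= 0):
        raise ValueError("power-law fit requires strictly positive k and C(k)")
    res = stats.linregress(np.log10(k), np.log10(c))
    return -float(res.slope), float(res.rvalue) ** 2


def fit_clustering_power_law(network: nx.Graph) -> tuple[float, float]:
    """Exponent w of C(k) ~ k^-w from raw integer-degree bins.

    Bins with k < 2 (clustering undefined in substance) or C(k) = 0 (log
    transform impossible) are excluded; fewer than 3 surviving bins is an
    error.
    """
    ck = clustering_by_degree(network)
    pairs = [(k, c) for k, c in ck.items() if k >= 2 and c > 0.0]
    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} usable degree bins (need >= 3) for the C(k) fit"
        )
    k, c = zip(*pairs)
    return fit_power_law(k, c)
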