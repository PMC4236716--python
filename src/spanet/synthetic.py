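"""Synthetic benchmarks with planted ground truth for every pipeline stage.

The generator emulates the statistical structure each stage assumes, so the
whole pipeline is testable without any database download:

* a scale-free interactome (preferential attachment) with planted dense
  modules (cliques, lightly bridged to the background),
* a three-aspect GO-like annotation vocabulary in which seed ("core")
  proteins pool to a known core vocabulary and a known subset of proteins is
  constructed to satisfy the permissibility rule (``permissible_truth``),
* "unknown function" proteins — network-resident ones annotated to the root
  biological-process term only (so they can pass the permissibility rule and
  reach a module), plus a few off-network ones with a truly empty process
  set,
* a TF -> target regulatory network with a known active subset whose targets
  draw small p-values (two-sided normal test with a given noncentrality);
  all other genes draw uniform p-values.

A deterministic hierarchical (clique-replication) network is provided for
the C(k) ~ k^-w hierarchical-modularity test; its analytic target exponent
is ``HIERARCHICAL_TARGET_W = 1.0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .reporter import RegulatoryNetwork
from .spa import ROOT_PROCESS_TERM, AnnotationSet

#: Analytic C(k) ~ k^-w exponent of the deterministic hierarchical model.
HIERARCHICAL_TARGET_W = 1.0


@dataclass(frozen=True)
class GeneratorParams:
    n_proteins: int = 500
    attachment_edges: int = 3
    n_aspect_terms: tuple = (8, 8, 12)  # core vocabulary size per aspect (C, F, P)
    n_background_terms: int = 30  # non-core terms per aspect
    n_cores: int = 14
    permissible_fraction: float = 0.3
    n_planted_modules: int = 3
    module_size: int = 8
    #: plant cliques of sizes module_size, module_size+1, ... rather than one
    #: uniform size; exactly interchangeable complexes are unrealistic and
    #: make the dominant adjacency eigenpair degenerate
    graded_modules: bool = True
    n_tfs: int = 20
    targets_per_tf: int = 20
    n_active_tfs: int = 3
    active_tf_effect: float = 4.0
    unknown_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.permissible_fraction <= 1.0):
            raise ValueError("permissible_fraction must lie in [0, 1]")
        if not (0.0 <= self.unknown_fraction <= 1.0):
            raise ValueError("unknown_fraction must lie in [0, 1]")
        if self.module_size < 5:
            raise ValueError("module_size must be >= 5 to survive the module-size filter")


@dataclass
class SyntheticBenchmark:
    network: nx.Graph
    annotations: dict
    core_proteins: list
    permissible_truth: set
    planted_modules: list  # list of frozensets
    regnet: RegulatoryNetwork
    active_tfs: set
    gene_pvalues: dict
    unknown_truth: set = field(default_factory=set)
    planted_module_terms: list = field(default_factory=list)
    params: GeneratorParams = field(default_factory=GeneratorParams)

    def validate(self) -> None:
        if not set(self.core_proteins) <= self.permissible_truth:
            raise AssertionError("cores must be a subset of permissible_truth")
        for module in self.planted_modules:
            sub = self.network.subgraph(module)
            if not nx.is_connected(sub):
                raise AssertionError("planted module is not connected")
            if nx.density(sub) < 0.8:
                raise AssertionError("planted module density < 0.8")
        for protein, ann in self.annotations.items():
            if protein in self.unknown_truth:
                continue
            if not (ann.component_terms and ann.function_terms and ann.process_terms):
                raise AssertionError(f"protein {protein} lacks an aspect annotation")
        for gene, p in self.gene_pvalues.items():
            if not (0.0 < p <= 1.0):
                raise AssertionError(f"gene {gene}: p-value {p} outside (0, 1]")
        if not self.active_tfs <= self.regnet.tfs:
            raise AssertionError("active TFs must appear in the regulatory network")


def _protein_name(i: int) -> str:
    return f"P{i:04d}"


def generate_ppi(params: GeneratorParams) -> nx.Graph:
    """Scale-free interactome by preferential attachment (connected, simple)."""
    if params.n_proteins < 10:
        raise ValueError("n_proteins must be >= 10")
    if params.attachment_edges >= params.n_proteins:
        raise ValueError("attachment_edges must be < n_proteins")
    raw = nx.barabasi_albert_graph(
        params.n_proteins, params.attachment_edges, seed=params.seed
    )
    return nx.relabel_nodes(raw, {i: _protein_name(i) for i in raw.nodes()})


def plant_modules(
    network: nx.Graph, params: GeneratorParams, seed: int | None = None
) -> tuple[nx.Graph, list[frozenset]]:
    """Plant disjoint cliques, each tied to the background by few bridges.

    Each planted member set is completed to a clique after stripping its
    prior edges; every module keeps between 1 and module_size/2 bridge edges
    to distinct non-module background nodes.  Background connectivity is
    repaired (through non-module nodes) if edge stripping fragmented it.
    """
    if params.graded_modules:
        sizes = [params.module_size + i for i in range(params.n_planted_modules)]
    else:
        sizes = [params.module_size] * params.n_planted_modules
    total = sum(sizes)
    if total > network.number_of_nodes() / 2:
        raise ValueError("planted modules would cover more than half the network")
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    G = network.copy()

    # draw members from the low-degree half so stripping edges stays benign
    by_degree = sorted(G.nodes(), key=lambda v: (G.degree(v), v))
    pool = by_degree[: max(total, len(by_degree) // 2)]
    chosen = rng.choice(len(pool), size=total, replace=False)
    members_flat = [pool[i] for i in sorted(chosen)]
    modules = []
    start = 0
    for size in sizes:
        modules.append(frozenset(members_flat[start : start + size]))
        start += size
    module_nodes = set(members_flat)

    outside = sorted(set(G.nodes()) - module_nodes)
    for module in modules:
        for v in sorted(module):
            G.remove_edges_from(list(G.edges(v)))
        mem = sorted(module)
        for i, a in enumerate(mem):
            for b in mem[i + 1 :]:
                G.add_edge(a, b)
        n_bridges = int(1 + rng.integers(0, len(mem) // 2))
        anchors = rng.choice(len(mem), size=n_bridges, replace=False)
        partners = rng.choice(len(outside), size=n_bridges, replace=False)
        for ai, pi in zip(sorted(anchors), sorted(partners)):
            G.add_edge(mem[ai], outside[pi])

    # reconnect any background fragments through non-module nodes
    components = sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c)))
    main = components[0]
    main_anchor = min(n for n in main if n not in module_nodes)
    for comp in components[1:]:
        free = sorted(n for n in comp if n not in module_nodes)
        anchor = free[0] if free else min(comp)
        G.add_edge(anchor, main_anchor)
    return G, modules


def _core_vocabulary(params: GeneratorParams) -> dict[str, list[str]]:
    nc, nf, np_ = params.n_aspect_terms
    vocab = {
        "C": [f"GO:{1000000 + i:07d}" for i in range(nc)],
        "F": [f"GO:{2000000 + i:07d}" for i in range(nf)],
        "P": [f"GO:{3000000 + i:07d}" for i in range(np_ - 1)] + [ROOT_PROCESS_TERM],
    }
    return vocab


def _background_vocabulary(params: GeneratorParams) -> dict[str, list[str]]:
    n = params.n_background_terms
    return {
        "C": [f"GO:{5000000 + i:07d}" for i in range(n)],
        "F": [f"GO:{6000000 + i:07d}" for i in range(n)],
        "P": [f"GO:{7000000 + i:07d}" for i in range(n)],
    }


def generate_annotations(
    network: nx.Graph,
    cores: list[str],
    params: GeneratorParams,
    seed: int | None = None,
    force_permissible: set | None = None,
    force_unknown: set | None = None,
) -> tuple[dict, set, set]:
    """Annotations with a planted permissible subset and unknown-function set.

    Returns ``(annotations, permissible_truth, unknown_truth)``.  Core
    proteins draw exclusively from the core vocabulary and jointly cover it
    exactly; a ``permissible_fraction`` Bernoulli draw (plus any forced
    proteins) yields non-cores carrying >= 1 core-vocabulary term in every
    aspect; every other protein has at least one aspect devoid of
    core-vocabulary terms.  Unknown-function proteins drawn from the
    permissible set are annotated to the root process term only.
    """
    if not cores:
        raise ValueError("core protein list is empty")
    rng = np.random.default_rng(params.seed + 2 if seed is None else seed)
    force_permissible = set(force_permissible or ())
    force_unknown = set(force_unknown or ())
    core_vocab = _core_vocabulary(params)
    bg_vocab = _background_vocabulary(params)
    aspects = ("C", "F", "P")

    annotations: dict[str, dict[str, set]] = {
        p: {a: set() for a in aspects} for p in sorted(network.nodes())
    }

    # cores: cover the core vocabulary exactly (round-robin) + 1 random term/aspect
    for aspect in aspects:
        vocab = core_vocab[aspect]
        for i, term in enumerate(vocab):
            annotations[cores[i % len(cores)]][aspect].add(term)
        for core in cores:
            annotations[core][aspect].add(vocab[int(rng.integers(0, len(vocab)))])

    non_cores = [p for p in sorted(network.nodes()) if p not in set(cores)]
    bernoulli = rng.random(len(non_cores)) < params.permissible_fraction
    permissible = {p for p, keep in zip(non_cores, bernoulli) if keep} | force_permissible
    permissible -= set(cores)

    for p in non_cores:
        if p in permissible:
            for aspect in aspects:
                picks = rng.choice(len(core_vocab[aspect]), size=int(1 + rng.integers(0, 2)), replace=False)
                annotations[p][aspect].update(core_vocab[aspect][i] for i in picks)
                if rng.random() < 0.5:
                    annotations[p][aspect].add(bg_vocab[aspect][int(rng.integers(0, len(bg_vocab[aspect])))])
        else:
            blocked = {aspects[int(rng.integers(0, 3))]}
            for aspect in aspects:
                if aspect in blocked or rng.random() < 0.5:
                    picks = rng.choice(len(bg_vocab[aspect]), size=int(1 + rng.integers(0, 2)), replace=False)
                    annotations[p][aspect].update(bg_vocab[aspect][i] for i in picks)
                else:
                    annotations[p][aspect].add(core_vocab[aspect][int(rng.integers(0, len(core_vocab[aspect])))])
                    annotations[p][aspect].add(bg_vocab[aspect][int(rng.integers(0, len(bg_vocab[aspect])))])

    permissible_truth = permissible | set(cores)

    # unknown-function proteins: root-only process annotation, still permissible
    eligible = sorted(permissible - force_unknown)
    n_unknown = int(round(params.unknown_fraction * len(permissible)))
    extra = max(0, n_unknown - len(force_unknown))
    picks = rng.choice(len(eligible), size=min(extra, len(eligible)), replace=False)
    unknown_truth = force_unknown | {eligible[i] for i in sorted(picks)}
    for p in unknown_truth:
        annotations[p]["P"] = {ROOT_PROCESS_TERM}

    # a couple of clearly off-pipeline proteins with truly empty process sets
    non_perm = sorted(set(non_cores) - permissible)
    for p in non_perm[:2]:
        annotations[p]["P"] = set()
        unknown_truth.add(p)

    out = {
        p: AnnotationSet(frozenset(d["C"]), frozenset(d["F"]), frozenset(d["P"]))
        for p, d in annotations.items()
    }
    return out, permissible_truth, unknown_truth


def generate_regnet(
    params: GeneratorParams, genes: list[str], seed: int | None = None
) -> RegulatoryNetwork:
    """TF -> target edges; TFs get distinct random target sets from ``genes``."""
    rng = np.random.default_rng(params.seed + 3 if seed is None else seed)
    genes = sorted(genes)
    edges = []
    for t in range(params.n_tfs):
        tf = f"TF{t:03d}"
        picks = rng.choice(len(genes), size=min(params.targets_per_tf, len(genes)), replace=False)
        edges.extend((tf, genes[i]) for i in sorted(picks))
    return RegulatoryNetwork.from_edges(edges)


def generate_expression(
    regnet: RegulatoryNetwork,
    active_tfs: set,
    effect: float,
    seed: int,
    genes: list[str] | None = None,
) -> dict[str, float]:
    """Gene -> p-value map with planted active regulators.

    Targets of active TFs draw p = two-sided normal-test p-values of
    N(effect, 1) draws; every other gene draws uniform(0, 1] p-values.
    """
    if effect <= 0:
        raise ValueError("effect must be > 0")
    if not set(active_tfs) <= regnet.tfs:
        raise ValueError("active_tfs must be a subset of the regnet TFs")
    rng = np.random.default_rng(seed)
    universe = sorted(set(genes) if genes is not None else {t for _, t in regnet.edges})
    active_targets = set()
    for tf in sorted(active_tfs):
        active_targets |= regnet.targets(tf)
    out: dict[str, float] = {}
    for gene in universe:
        if gene in active_targets:
            z = effect + rng.standard_normal()
            p = 2.0 * float(stats.norm.sf(abs(z)))
            out[gene] = max(p, 1e-300)
        else:
            out[gene] = 1.0 - float(rng.random())  # uniform on (0, 1]
    return out


def hierarchical_network(iterations: int = 3, base_size: int = 5) -> nx.Graph:
    """Deterministic hierarchical clique-replication network.

    Starts from a clique of ``base_size`` nodes and, at each iteration,
    attaches ``base_size - 1`` replicas whose peripheral nodes all link to
    the original central hub.  The mean clustering coefficient decays as
    C(k) ~ k^-1 with degree, the hierarchical-modularity signature
    (:data:`HIERARCHICAL_TARGET_W`).
    """
    if base_size < 3 or iterations < 1:
        raise ValueError("need base_size >= 3 and iterations >= 1")
    G = nx.complete_graph(base_size)
    peripheral = list(range(1, base_size))  # node 0 is the hub
    for _ in range(iterations):
        size = G.number_of_nodes()
        new_peripheral = []
        for rep in range(1, base_size):
            offset = rep * size
            G.add_edges_from((u + offset, v + offset) for u, v in list(G.edges()) if max(u, v) < size)
            new_peripheral.extend(p + offset for p in peripheral)
        for p in new_peripheral:
            G.add_edge(p, 0)
        peripheral = new_peripheral
    return nx.relabel_nodes(G, {i: f"H{i:05d}" for i in G.nodes()})


def make_benchmark(params: GeneratorParams = GeneratorParams()) -> SyntheticBenchmark:
    """Assemble the full benchmark; all stages' ground truth is recorded."""
    base = generate_ppi(params)
    network, modules = plant_modules(base, params)
    module_nodes = set().union(*modules) if modules else set()

    rng = np.random.default_rng(params.seed + 4)
    candidates = sorted(set(network.nodes()) - module_nodes)
    picks = rng.choice(len(candidates), size=params.n_cores, replace=False)
    cores = [candidates[i] for i in sorted(picks)]

    # one unknown-function protein planted inside each module
    force_unknown = {min(m) for m in modules}
    annotations, permissible_truth, unknown_truth = generate_annotations(
        network,
        cores,
        params,
        force_permissible=module_nodes,
        force_unknown=force_unknown,
    )

    # Real seed-anchored networks are essentially one connected component:
    # upgrade shortest-path nodes to permissible until every core and every
    # planted module lies in the giant admitted component.
    core_vocab = _core_vocabulary(params)
    anchors = list(cores) + [min(m) for m in modules]
    while True:
        H = network.subgraph(permissible_truth)
        comps = sorted(nx.connected_components(H), key=lambda c: (-len(c), min(c)))
        giant = comps[0]
        pending = [a for a in anchors if a not in giant]
        if not pending:
            break
        paths = nx.single_source_shortest_path(network, pending[0])
        reach = min(
            (t for t in paths if t in giant), key=lambda t: (len(paths[t]), t)
        )
        for p in paths[reach]:
            if p in permissible_truth:
                continue
            ann = annotations[p]
            annotations[p] = AnnotationSet(
                ann.component_terms | {core_vocab["C"][0]},
                ann.function_terms | {core_vocab["F"][0]},
                ann.process_terms | {core_vocab["P"][0]},
            )
            permissible_truth.add(p)
            unknown_truth.discard(p)

    # each planted module shares a dedicated process term (its "function"),
    # so the enrichment stage has a planted signal to recover
    planted_module_terms = []
    for i, module in enumerate(modules):
        term = f"GO:{3900000 + i:07d}"
        planted_module_terms.append(term)
        for p in module:
            if p in unknown_truth:
                continue
            ann = annotations[p]
            annotations[p] = AnnotationSet(
                ann.component_terms, ann.function_terms, ann.process_terms | {term}
            )

    regnet = generate_regnet(params, sorted(network.nodes()))
    active_tfs = {f"TF{t:03d}" for t in range(params.n_active_tfs)}
    gene_pvalues = generate_expression(
        regnet,
        active_tfs,
        params.active_tf_effect,
        params.seed + 5,
        genes=sorted(network.nodes()),
    )

    bench = SyntheticBenchmark(
        network=network,
        annotations=annotations,
        core_proteins=cores,
        permissible_truth=permissible_truth,
        planted_modules=modules,
        regnet=regnet,
        active_tfs=active_tfs,
        gene_pvalues=gene_pvalues,
        unknown_truth=unknown_truth,
        planted_module_terms=planted_module_terms,
        params=params,
    )
    bench.validate()
    return bench


def write_benchmark(bench: SyntheticBenchmark, out_dir) -> dict:
    """Emit the benchmark as plain-text files; returns the path map."""
    from pathlib import Path

    from . import io as spio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": out_dir / "ppi_edges.tsv",
        "gaf": out_dir / "annotations.gaf",
        "cores": out_dir / "cores.txt",
        "regnet": out_dir / "regnet.tsv",
        "pvalues": out_dir / "pvalues.tsv",
        "truth": out_dir / "truth.tsv",
    }
    spio.write_network(bench.network, paths["ppi"], format="edge_tsv")
    spio.write_gaf(bench.annotations, paths["gaf"])
    paths["cores"].write_text("".join(f"{c}\n" for c in bench.core_proteins))
    with paths["regnet"].open("w") as fh:
        fh.write("#tf\ttarget\n")
        for tf, tg in sorted(bench.regnet.edges):
            fh.write(f"{tf}\t{tg}\n")
    with paths["pvalues"].open("w") as fh:
        fh.write("#gene\tp_value\n")
        for gene in sorted(bench.gene_pvalues):
            fh.write(f"{gene}\t{bench.gene_pvalues[gene]:.10g}\n")
    with paths["truth"].open("w") as fh:
        fh.write("#kind\tidentifier\tdetail\n")
        for p in sorted(bench.permissible_truth):
            fh.write(f"permissible\t{p}\t-\n")
        for i, module in enumerate(bench.planted_modules, start=1):
            for p in sorted(module):
                fh.write(f"planted_module\t{p}\t{i}\n")
        for p in sorted(bench.unknown_truth):
            fh.write(f"unknown_function\t{p}\t-\n")
        for tf in sorted(bench.active_tfs):
            fh.write(f"active_tf\t{tf}\t-\n")
    return paths
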