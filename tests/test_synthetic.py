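import networkx as nx
import numpy as np
import pytest
from scipy import stats

from spanet.spa import ROOT_PROCESS_TERM, build_annotation_table, is_permissible
from spanet.synthetic import (
    GeneratorParams,
    generate_annotations,
    generate_ppi,
    hierarchical_network,
    make_benchmark,
    plant_modules,
)


class TestGeneratePpi:
    def test_deterministic(self):
        p = GeneratorParams(n_proteins=500, seed=4)
        a, b = generate_ppi(p), generate_ppi(p)
        assert set(a.edges()) == set(b.edges())

    def test_handshake_lemma(self):
        g = generate_ppi(GeneratorParams(n_proteins=200, seed=1))
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()

    def test_heavy_tail(self):
        g = generate_ppi(GeneratorParams(n_proteins=500, seed=0))
        degrees = sorted(d for _, d in g.degree())
        assert degrees[-1] >= 5 * degrees[len(degrees) // 2]

    def test_log_log_degree_slope(self):
        g = generate_ppi(GeneratorParams(n_proteins=2000, seed=0))
        from collections import Counter

        counts = Counter(d for _, d in g.degree())
        ks = np.array(sorted(counts))
        cs = np.array([counts[k] for k in ks], dtype=float)
        res = stats.linregress(np.log10(ks), np.log10(cs))
        assert -3.5 <= res.slope <= -1.5

    def test_attachment_edges_bound(self):
        with pytest.raises(ValueError):
            generate_ppi(GeneratorParams(n_proteins=10, attachment_edges=10))


class TestPlantModules:
    def test_planted_cliques_have_density_one(self):
        params = GeneratorParams(n_proteins=300, seed=6)
        network, modules = plant_modules(generate_ppi(params), params)
        for module in modules:
            assert nx.density(network.subgraph(module)) == 1.0

    def test_modules_disjoint(self):
        params = GeneratorParams(n_proteins=300, seed=6)
        _, modules = plant_modules(generate_ppi(params), params)
        seen = set()
        for module in modules:
            assert not (module & seen)
            seen |= module

    def test_bridge_count_bounds(self):
        params = GeneratorParams(n_proteins=300, seed=6)
        network, modules = plant_modules(generate_ppi(params), params)
        for module in modules:
            bridges = [
                e for e in network.edges(module) if len(set(e) & module) == 1
            ]
            assert 1 <= len(bridges) <= len(module) / 2

    def test_network_stays_connected(self):
        params = GeneratorParams(n_proteins=300, seed=6)
        network, _ = plant_modules(generate_ppi(params), params)
        assert nx.is_connected(network)

    def test_infeasible_coverage_rejected(self):
        params = GeneratorParams(
            n_proteins=40, n_planted_modules=4, module_size=8, graded_modules=False
        )
        with pytest.raises(ValueError):
            plant_modules(generate_ppi(params), params)


class TestGenerateAnnotations:
    def test_cores_satisfy_their_own_rule(self, benchmark):
        table = build_annotation_table(benchmark.core_proteins, benchmark.annotations)
        for core in benchmark.core_proteins:
            assert is_permissible(benchmark.annotations[core], table)

    def test_non_permissible_proteins_fail_the_rule(self, benchmark):
        table = build_annotation_table(benchmark.core_proteins, benchmark.annotations)
        outside = set(benchmark.network.nodes()) - benchmark.permissible_truth
        assert outside, "benchmark should contain non-permissible proteins"
        for protein in sorted(outside)[:50]:
            assert not is_permissible(benchmark.annotations[protein], table)

    def test_permissible_count_tracks_binomial_expectation(self):
        params = GeneratorParams(n_proteins=1000, permissible_fraction=0.3, seed=0)
        network = generate_ppi(params)
        cores = sorted(network.nodes())[: params.n_cores]
        _, permissible, _ = generate_annotations(network, cores, params)
        observed = len(permissible - set(cores))
        expected = 0.3 * (1000 - params.n_cores)
        assert abs(observed - expected) <= 0.05 * expected

    def test_empty_core_list_rejected(self):
        params = GeneratorParams(n_proteins=50)
        network = generate_ppi(params)
        with pytest.raises(ValueError):
            generate_annotations(network, [], params)


class TestBenchmark:
    def test_invariants_hold(self, benchmark):
        benchmark.validate()

    def test_unknowns_are_root_only_or_empty(self, benchmark):
        for protein in benchmark.unknown_truth:
            proc = benchmark.annotations[protein].process_terms
            assert proc in (frozenset(), frozenset({ROOT_PROCESS_TERM}))

    def test_each_planted_module_has_an_unknown_member(self, benchmark):
        for module in benchmark.planted_modules:
            assert module & benchmark.unknown_truth

    def test_deterministic(self):
        a = make_benchmark(GeneratorParams(n_proteins=120, seed=9))
        b = make_benchmark(GeneratorParams(n_proteins=120, seed=9))
        assert set(a.network.edges()) == set(b.network.edges())
        assert a.annotations == b.annotations
        assert a.gene_pvalues == b.gene_pvalues


class TestHierarchicalNetwork:
    def test_size_grows_geometrically(self):
        assert hierarchical_network(1).number_of_nodes() == 25
        assert hierarchical_network(2).number_of_nodes() == 125
        assert hierarchical_network(3).number_of_nodes() == 625

    def test_deterministic(self):
        a, b = hierarchical_network(2), hierarchical_network(2)
        assert set(a.edges()) == set(b.edges())
        assert nx.is_connected(a)
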