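import math

import networkx as nx
import numpy as np
import pytest

from spanet.tuning import (
    EvcEnsemble,
    build_ensemble,
    degree_preserving_randomize,
    eigenvector_centrality,
    tune,
)

from .oracles import dense_evc, independent_tuning_test


class TestEigenvectorCentrality:
    def test_triangle_symmetry(self):
        evc = eigenvector_centrality(nx.complete_graph(3))
        for v in evc.values():
            assert v == pytest.approx(1 / math.sqrt(3), abs=1e-10)

    def test_path_frozen_values(self):
        # principal eigenvector of P3: (1, sqrt(2), 1)/2
        evc = eigenvector_centrality(nx.path_graph(["A", "B", "C"]))
        assert evc["A"] == pytest.approx(0.5, abs=1e-9)
        assert evc["B"] == pytest.approx(math.sqrt(2) / 2, abs=1e-9)
        assert evc["C"] == pytest.approx(0.5, abs=1e-9)

    def test_star_frozen_values(self):
        evc = eigenvector_centrality(nx.star_graph(4))
        assert evc[0] == pytest.approx(math.sqrt(2) / 2, abs=1e-9)
        for leaf in range(1, 5):
            assert evc[leaf] == pytest.approx(math.sqrt(2) / 4, abs=1e-9)

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_dense_eigensolver(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        p = float(rng.uniform(0.15, 0.6))
        g = nx.gnp_random_graph(n, p, seed=seed)
        while not nx.is_connected(g):
            seed += 1000
            g = nx.gnp_random_graph(n, p, seed=seed)
        mine = eigenvector_centrality(g)
        ref = dense_evc(g)
        assert max(abs(mine[v] - ref[v]) for v in g.nodes()) < 1e-8

    def test_bipartite_graph_converges(self):
        # cycle of even length is bipartite; the +1 shift must prevent oscillation
        evc = eigenvector_centrality(nx.cycle_graph(8))
        ref = dense_evc(nx.cycle_graph(8))
        assert max(abs(evc[v] - ref[v]) for v in range(8)) < 1e-8

    def test_l2_normalized_nonnegative(self):
        evc = eigenvector_centrality(nx.gnp_random_graph(30, 0.2, seed=1))
        values = np.array(list(evc.values()))
        assert np.all(values >= 0)
        assert np.sum(values**2) == pytest.approx(1.0, abs=1e-8)


class TestDegreePreservingRandomize:
    def test_triangle_forced_outcome(self):
        tri = nx.complete_graph(3)
        out = degree_preserving_randomize(tri, seed=0)
        assert set(map(frozenset, out.edges())) == set(map(frozenset, tri.edges()))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_degree_sequence_conserved_exactly(self, seed, benchmark):
        g = benchmark.network
        out = degree_preserving_randomize(g, seed=seed)
        assert dict(out.degree()) == dict(g.degree())
        assert nx.number_of_selfloops(out) == 0

    def test_two_seeds_mix_the_edges(self, benchmark):
        g = benchmark.network
        e1 = {frozenset(e) for e in degree_preserving_randomize(g, seed=1).edges()}
        e2 = {frozenset(e) for e in degree_preserving_randomize(g, seed=2).edges()}
        assert len(e1 ^ e2) >= 0.1 * 2 * g.number_of_edges()

    def test_deterministic_for_fixed_seed(self, benchmark):
        g = benchmark.network
        a = degree_preserving_randomize(g, seed=5)
        b = degree_preserving_randomize(g, seed=5)
        assert set(map(frozenset, a.edges())) == set(map(frozenset, b.edges()))


class TestEnsembleAndTune:
    def test_every_node_has_R_samples(self):
        g = nx.gnp_random_graph(25, 0.25, seed=2)
        ens = build_ensemble(g, R=10, seed=0)
        assert all(len(s) == 10 for s in ens.samples.values())

    def test_invariant_graph_gives_observed_samples(self):
        tri = nx.complete_graph(3)
        ens = build_ensemble(tri, R=5, seed=0)
        for node in tri.nodes():
            assert np.allclose(ens.samples[node], ens.observed[node])

    def test_r_below_two_rejected(self):
        with pytest.raises(ValueError):
            build_ensemble(nx.complete_graph(4), R=1, seed=0)

    def test_ensemble_deterministic(self):
        g = nx.gnp_random_graph(20, 0.3, seed=3)
        a = build_ensemble(g, R=5, seed=9)
        b = build_ensemble(g, R=5, seed=9)
        for node in g.nodes():
            assert np.array_equal(a.samples[node], b.samples[node])

    def _fake_ensemble(self, samples_by_node, observed):
        g = nx.path_graph(sorted(samples_by_node))
        return EvcEnsemble(
            network=g,
            observed=observed,
            samples={k: np.asarray(v, dtype=float) for k, v in samples_by_node.items()},
            R=len(next(iter(samples_by_node.values()))),
        )

    def test_zero_variance_equal_to_observed_dropped(self):
        ens = self._fake_ensemble(
            {"A": [0.5] * 10, "B": [0.5] * 10, "C": [0.5] * 10},
            {"A": 0.5, "B": 0.5, "C": 0.5},
        )
        tuned, records = tune(ens, alpha=0.0001)
        assert all(not r.retained and r.p_value == 1.0 for r in records)
        assert tuned.number_of_nodes() == 0

    def test_zero_variance_different_from_observed_kept(self):
        ens = self._fake_ensemble(
            {"A": [0.5] * 10, "B": [0.5] * 10, "C": [0.5] * 10},
            {"A": 0.9, "B": 0.5, "C": 0.9},
        )
        _, records = tune(ens, alpha=0.0001)
        by_node = {r.node: r for r in records}
        assert by_node["A"].retained and by_node["A"].p_value == 0.0
        assert not by_node["B"].retained

    def test_ten_sd_outlier_retained_at_alpha(self):
        rng = np.random.default_rng(0)
        samples = 0.3 + 0.01 * rng.standard_normal(100)
        observed = float(samples.mean() + 10 * samples.std(ddof=1))
        ens = self._fake_ensemble(
            {"A": samples, "B": samples}, {"A": observed, "B": float(samples.mean())}
        )
        _, records = tune(ens, alpha=0.0001)
        by_node = {r.node: r for r in records}
        assert by_node["A"].retained
        assert not by_node["B"].retained

    def test_retention_matches_independent_recomputation(self, benchmark):
        from spanet.spa import reconstruct

        etn = reconstruct(
            benchmark.core_proteins,
            benchmark.annotations,
            list(benchmark.network.edges()),
        )
        ens = build_ensemble(etn, R=30, seed=4)
        _, records = tune(ens, alpha=0.0001)
        for rec in records:
            expect_retained, expect_p = independent_tuning_test(
                ens.observed[rec.node], ens.samples[rec.node], 0.0001
            )
            assert rec.retained == expect_retained
            assert rec.p_value == pytest.approx(expect_p, rel=1e-9)

    def test_tuned_network_is_induced_subgraph(self):
        g = nx.gnp_random_graph(30, 0.2, seed=6)
        ens = build_ensemble(g, R=10, seed=0)
        tuned, records = tune(ens, alpha=0.05)
        retained = {r.node for r in records if r.retained}
        assert set(tuned.nodes()) == retained
        for u, v in g.subgraph(retained).edges():
            assert tuned.has_edge(u, v)

    def test_retention_shrinks_as_alpha_shrinks(self):
        g = nx.gnp_random_graph(40, 0.15, seed=8)
        ens = build_ensemble(g, R=20, seed=1)
        sizes = []
        for alpha in (0.2, 0.05, 0.001, 0.0001):
            tuned, _ = tune(ens, alpha=alpha)
            sizes.append(tuned.number_of_nodes())
        assert sizes == sorted(sizes, reverse=True)
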