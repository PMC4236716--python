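import numpy as np
import pytest
from hypothesis import given, strategies as st

from spanet.enrichment import (
    bh_adjust,
    enrich_modules,
    hypergeometric_p,
    unknown_function_candidates,
)
from spanet.mcode import Module
from spanet.spa import ROOT_PROCESS_TERM, AnnotationSet

from .oracles import exhaustive_hypergeom_upper, stepup_bh


def _ann(p=()):
    return AnnotationSet.from_terms(process=p)


class TestHypergeometric:
    def test_certain_event(self):
        assert hypergeometric_p(5, 5, 100, 100) == 1.0

    def test_k_zero(self):
        assert hypergeometric_p(0, 5, 10, 50) == 1.0

    def test_exhaustive_sum_example(self):
        expected = exhaustive_hypergeom_upper(3, 5, 5, 50)
        assert hypergeometric_p(3, 5, 5, 50) == pytest.approx(expected, rel=1e-12)

    def test_bounds_violation_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_p(6, 5, 10, 50)
        with pytest.raises(ValueError):
            hypergeometric_p(1, 5, 60, 50)

    def test_matches_exhaustive_oracle_across_grid(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            N = int(rng.integers(2, 201))
            n = int(rng.integers(1, N + 1))
            K = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            expected = exhaustive_hypergeom_upper(k, n, K, N)
            assert hypergeometric_p(k, n, K, N) == pytest.approx(
                expected, rel=1e-10, abs=1e-300
            )


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_oracle_agreement_and_invariants(self, ps):
        qs = bh_adjust(ps)
        expected = stepup_bh(ps)
        assert qs == pytest.approx(expected, abs=1e-12)
        for p, q in zip(ps, qs):
            assert q >= p - 1e-12
            assert 0.0 <= q <= 1.0
        # adjustment preserves the significance ordering of the inputs
        order = sorted(range(len(ps)), key=lambda i: ps[i])
        sorted_qs = [qs[i] for i in order]
        assert sorted_qs == sorted(sorted_qs)
        # constant lists are fixed points of the step-up procedure
        if ps and len(set(ps)) == 1:
            assert qs == pytest.approx(ps, abs=1e-12)


class TestEnrichModules:
    def _reference(self, n_total, term, n_with_term):
        annotations = {}
        for i in range(n_total):
            name = f"G{i:03d}"
            terms = {term} if i < n_with_term else {f"GO:000000{i % 5}"}
            annotations[name] = _ann(terms)
        return annotations

    def test_fully_concentrated_term_reported(self):
        annotations = self._reference(100, "GO:1111111", 5)
        module = Module(frozenset(f"G{i:03d}" for i in range(5)), "G000", 5.0, 1)
        records = enrich_modules([module], annotations, sorted(annotations), alpha=0.0001)
        assert any(r.term == "GO:1111111" for r in records)
        rec = next(r for r in records if r.term == "GO:1111111")
        assert (rec.k, rec.n, rec.K, rec.N) == (5, 5, 5, 100)
        assert rec.p_value == pytest.approx(
            exhaustive_hypergeom_upper(5, 5, 5, 100), rel=1e-10
        )

    def test_small_module_skipped(self):
        annotations = self._reference(100, "GO:1111111", 4)
        module = Module(frozenset(f"G{i:03d}" for i in range(4)), "G000", 4.0, 1)
        assert enrich_modules([module], annotations, sorted(annotations), min_size=5) == []

    def test_proportional_module_yields_nothing(self):
        # module term frequencies identical to the reference proportions
        annotations = {f"G{i:02d}": _ann({f"GO:000000{i % 2}"}) for i in range(40)}
        module = Module(frozenset(f"G{i:02d}" for i in range(10)), "G00", 5.0, 1)
        assert enrich_modules([module], annotations, sorted(annotations), alpha=0.0001) == []

    def test_invariant_under_member_reordering(self):
        annotations = self._reference(60, "GO:1111111", 6)
        members = [f"G{i:03d}" for i in range(6)]
        m1 = Module(frozenset(members), "G000", 6.0, 1)
        m2 = Module(frozenset(reversed(members)), "G000", 6.0, 1)
        ref = sorted(annotations)
        assert enrich_modules([m1], annotations, ref) == enrich_modules([m2], annotations, ref)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            enrich_modules([], {}, [])

    def test_q_never_below_p(self, benchmark):
        from spanet.mcode import find_modules

        modules = find_modules(benchmark.network)
        reference = [
            p for p in benchmark.network.nodes()
            if benchmark.annotations[p].process_terms
        ]
        records = enrich_modules(
            modules, benchmark.annotations, reference, alpha=1.0, min_size=5
        )
        assert records, "expected at least the planted module terms"
        for r in records:
            assert r.q_value >= r.p_value - 1e-12
            assert r.k <= min(r.n, r.K)
            assert r.n <= r.N


class TestCandidates:
    def test_empty_process_set_listed(self):
        annotations = {f"G{i}": _ann({"GO:0000001"}) for i in range(6)}
        annotations["G0"] = _ann(())
        module = Module(frozenset(f"G{i}" for i in range(6)), "G1", 6.0, 1)
        (cand,) = unknown_function_candidates([module], annotations)
        assert (cand.protein, cand.reason) == ("G0", "no_process_annotation")

    def test_root_only_listed(self):
        annotations = {f"G{i}": _ann({"GO:0000001"}) for i in range(6)}
        annotations["G3"] = _ann({ROOT_PROCESS_TERM})
        module = Module(frozenset(f"G{i}" for i in range(6)), "G1", 6.0, 1)
        (cand,) = unknown_function_candidates([module], annotations)
        assert (cand.protein, cand.reason) == ("G3", "root_only")

    def test_small_modules_not_scanned(self):
        annotations = {f"G{i}": _ann(()) for i in range(4)}
        module = Module(frozenset(annotations), "G0", 4.0, 1)
        assert unknown_function_candidates([module], annotations, min_size=5) == []

    def test_benchmark_truth_recovered_exactly(self, benchmark):
        from spanet.mcode import find_modules
        from spanet.spa import reconstruct
        from spanet.tuning import build_ensemble, tune

        etn = reconstruct(
            benchmark.core_proteins,
            benchmark.annotations,
            list(benchmark.network.edges()),
        )
        ens = build_ensemble(etn, R=100, seed=0)
        tetn, _ = tune(ens, alpha=0.0001)
        modules = find_modules(tetn)
        candidates = unknown_function_candidates(modules, benchmark.annotations)
        reported_members = set().union(
            *(m.members for m in modules if m.size >= 5)
        ) if modules else set()
        expected = benchmark.unknown_truth & reported_members
        assert {c.protein for c in candidates} == expected
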