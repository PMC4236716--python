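"""Per-module GO biological-process enrichment and candidate extraction.

Over-representation of a term within a module is scored with the
hypergeometric upper tail against a reference universe — the annotated
proteins of the analyzed network ("whole annotation as reference set") —
with Benjamini–Hochberg FDR control applied within each module's family of
tested terms.  Modules below the minimum size are skipped.  Candidate
proteins are module members with no informative biological-process
annotation: an empty process set, or the root process term alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mcode import Module
from .spa import ROOT_PROCESS_TERM, AnnotationSet


@dataclass(frozen=True)
class EnrichmentRecord:
    module_rank: int
    term: str
    k: int  # module members carrying the term
    n: int  # annotated module members tested
    K: int  # reference proteins carrying the term
    N: int  # reference universe size
    p_value: float
    q_value: float


@dataclass(frozen=True)
class CandidateProtein:
    protein: str
    module_rank: int
    reason: str  # "no_process_annotation" | "root_only"


def hypergeometric_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), log-space stable."""
    if not (0 <= k <= min(n, K) and 0 < n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent hypergeometric parameters k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted values, input order preserved."""
    ps = list(p_values)
    if not ps:
        return []
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p!r} outside [0, 1]")
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    return [float(v) for v in q]


def enrich_modules(
    modules: Iterable[Module],
    annotations: Mapping[str, AnnotationSet],
    reference: Iterable[str],
    alpha: float = 0.0001,
    min_size: int = 5,
) -> list[EnrichmentRecord]:
    """Hypergeometric process-term enrichment of each sufficiently large module.

    ``reference`` is the protein universe the counts are taken against —
    normally every protein of the analyzed network carrying at least one
    process annotation.  Returns the records with ``q < alpha``, sorted by
    (module rank, q, term).
    """
    reference = sorted(set(reference))
    if not reference:
        raise ValueError("empty reference universe")
    N = len(reference)
    term_counts: Counter = Counter()
    for protein in reference:
        ann = annotations.get(protein)
        if ann is not None:
            term_counts.update(ann.process_terms)

    out: list[EnrichmentRecord] = []
    ref_set = set(reference)
    for module in modules:
        if module.size < min_size:
            continue
        tested = sorted(m for m in module.members if m in ref_set)
        n = len(tested)
        if n == 0:
            continue
        module_terms: Counter = Counter()
        for protein in tested:
            module_terms.update(annotations[protein].process_terms)
        terms = sorted(module_terms)
        if not terms:
            continue
        ps = [
            hypergeometric_p(module_terms[t], n, term_counts[t], N) for t in terms
        ]
        qs = bh_adjust(ps)
        for term, p, q in zip(terms, ps, qs):
            if q < alpha:
                out.append(
                    EnrichmentRecord(
                        module_rank=module.rank,
                        term=term,
                        k=module_terms[term],
                        n=n,
                        K=term_counts[term],
                        N=N,
                        p_value=p,
                        q_value=q,
                    )
                )
    out.sort(key=lambda r: (r.module_rank, r.q_value, r.term))
    return out


def unknown_function_candidates(
    modules: Iterable[Module],
    annotations: Mapping[str, AnnotationSet],
    min_size: int = 5,
    root_term: str = ROOT_PROCESS_TERM,
) -> list[CandidateProtein]:
    """Module members with no informative biological-process annotation.

    Only modules of at least ``min_size`` members are scanned (smaller ones
    are below the reporting threshold of the modular analysis).  Ordered by
    module rank, then protein id.
    """
    out: list[CandidateProtein] = []
    for module in modules:
        if module.size < min_size:
            continue
        for protein in sorted(module.members):
            ann = annotations.get(protein, AnnotationSet())
            proc = ann.process_terms
            if not proc:
                out.append(CandidateProtein(protein, module.rank, "no_process_annotation"))
            elif proc == {root_term}:
                out.append(CandidateProtein(protein, module.rank, "root_only"))
    out.sort(key=lambda c: (c.module_rank, c.protein))
    return out
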