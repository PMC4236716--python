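"""Selective Permissibility Algorithm: seed-anchored subnetwork reconstruction.

The algorithm pools the GO annotations of a small set of literature-curated
core proteins into an *annotation collection table* and admits any interactome
protein whose annotation set shares at least one term with the table in every
one of the three GO aspects (cellular component, molecular function,
biological process).  The phenotype-focused network is then the largest
connected component of the physical-interaction graph induced on the admitted
proteins.

Matching is literal set intersection on GO identifiers — no DAG ancestor
propagation.  Proteins lacking any annotation in some aspect can never be
permissible; core proteins bypass the rule but still need at least one
surviving interaction to appear in the result.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"^GO:\d{7}$")

#: Root biological-process term; proteins annotated to it alone are
#: "unknown function" in the candidate-extraction sense.
ROOT_PROCESS_TERM = "GO:0008150"


@dataclass(frozen=True)
class AnnotationSet:
    """Per-protein GO terms partitioned into the three ontology aspects."""

    component_terms: frozenset = frozenset()
    function_terms: frozenset = frozenset()
    process_terms: frozenset = frozenset()

    def aspect(self, code: str) -> frozenset:
        return {"C": self.component_terms, "F": self.function_terms, "P": self.process_terms}[code]

    @classmethod
    def from_terms(cls, component=(), function=(), process=()) -> "AnnotationSet":
        return cls(frozenset(component), frozenset(function), frozenset(process))


@dataclass(frozen=True)
class AnnotationTable:
    """Pooled (union) annotation sets of the core proteins, per aspect."""

    component_terms: frozenset
    function_terms: frozenset
    process_terms: frozenset
    n_core_proteins: int

    @property
    def n_terms(self) -> int:
        return len(self.component_terms) + len(self.function_terms) + len(self.process_terms)


def build_annotation_table(
    cores: Iterable[str], annotations: Mapping[str, AnnotationSet]
) -> AnnotationTable:
    """Pool the per-aspect annotations of the core proteins.

    Raises ``KeyError`` naming the first core protein missing from the
    annotation map.  Logs a warning when any pooled aspect is empty, because
    the permissibility rule would then reject every candidate.
    """
    cores = list(cores)
    if not cores:
        raise ValueError("core protein list is empty")
    comp: set = set()
    func: set = set()
    proc: set = set()
    for core in cores:
        if core not in annotations:
            raise KeyError(f"core protein {core!r} has no annotation record")
        ann = annotations[core]
        comp |= ann.component_terms
        func |= ann.function_terms
        proc |= ann.process_terms
    for name, terms in (("component", comp), ("function", func), ("process", proc)):
        if not terms:
            logger.warning(
                "annotation table has an empty %s aspect; "
                "no candidate can satisfy the permissibility rule",
                name,
            )
    return AnnotationTable(frozenset(comp), frozenset(func), frozenset(proc), len(cores))


def is_permissible(protein_annotations: AnnotationSet, table: AnnotationTable) -> bool:
    """True iff the protein shares >= 1 term with the table in all 3 aspects."""
    return bool(
        protein_annotations.component_terms & table.component_terms
        and protein_annotations.function_terms & table.function_terms
        and protein_annotations.process_terms & table.process_terms
    )


def reconstruct(
    cores: Iterable[str],
    annotations: Mapping[str, AnnotationSet],
    interactions: Iterable,
) -> nx.Graph:
    """Reconstruct the seed-anchored network from physical interactions.

    Parameters
    ----------
    cores
        Seed protein identifiers (bypass the permissibility rule).
    annotations
        Protein -> :class:`AnnotationSet`, covering at least the cores.
    interactions
        Iterable of :class:`~spanet.io.InteractionRecord` or plain
        ``(protein_a, protein_b)`` pairs.  Records carrying an
        ``interaction_class`` are filtered to physical ones.

    Returns
    -------
    networkx.Graph
        The largest connected component of the simple graph induced on the
        admitted candidate set (cores plus permissible proteins); self-loops
        and duplicate edges are discarded.  Cores without any surviving
        physical interaction are absent (and logged).
    """
    cores = list(dict.fromkeys(cores))
    table = build_annotation_table(cores, annotations)

    admitted = set(cores)
    for protein, ann in annotations.items():
        if protein not in admitted and is_permissible(ann, table):
            admitted.add(protein)

    graph = nx.Graph()
    n_pairs = 0
    for rec in interactions:
        if hasattr(rec, "protein_a"):
            a, b = rec.protein_a, rec.protein_b
            if getattr(rec.interaction_class, "value", rec.interaction_class) != "physical":
                continue
        else:
            a, b = rec
        n_pairs += 1
        if a == b:
            continue  # self-loop
        if a in admitted and b in admitted:
            graph.add_edge(a, b)
    if n_pairs == 0:
        raise ValueError("no interactions supplied")

    if graph.number_of_nodes() == 0:
        raise ValueError("reconstruction produced an empty network")

    components = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    largest = components[0]
    if len(components) > 1:
        logger.info(
            "keeping largest component (%d nodes); discarding %d smaller components",
            len(largest),
            len(components) - 1,
        )
    result = graph.subgraph(largest).copy()

    for core in cores:
        if core not in result:
            logger.warning(
                "core protein %s eliminated: no surviving physical interaction "
                "in the largest component",
                core,
            )
    logger.info(
        "reconstructed network: %d admitted candidates -> %d nodes, %d edges",
        len(admitted),
        result.number_of_nodes(),
        result.number_of_edges(),
    )
    return result
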