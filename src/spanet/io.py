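"""Readers and writers for the pipeline's external formats.

Supported formats: BioGrid TAB 2.0 interaction tables (read/write — the writer
exists so synthetic benchmarks can be round-tripped), GAF 2.x gene-association
files (read/write), SIF and two-column edge TSV networks (read/write), plain
newline-delimited identifier lists, TF->target regulatory edge TSVs, and
gene->p-value TSVs.

Identifier policy: systematic (ORF) names are the canonical node key; when a
BioGrid row carries both a systematic name and an official symbol, the
systematic name wins and the symbol is retained as an alias.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .spa import GO_ID_RE, AnnotationSet

logger = logging.getLogger(__name__)


class InteractionClass(enum.Enum):
    PHYSICAL = "physical"
    GENETIC = "genetic"
    OTHER = "other"


@dataclass(frozen=True)
class InteractionRecord:
    protein_a: str
    protein_b: str
    interaction_class: InteractionClass
    source_line: int


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# BioGrid TAB 2.0
# ---------------------------------------------------------------------------

#: Column count of the TAB 2.0 format.
TAB2_MIN_COLUMNS = 24
_TAB2_HEADER = (
    "#BioGRID Interaction ID\tEntrez Gene Interactor A\tEntrez Gene Interactor B\t"
    "BioGRID ID Interactor A\tBioGRID ID Interactor B\t"
    "Systematic Name Interactor A\tSystematic Name Interactor B\t"
    "Official Symbol Interactor A\tOfficial Symbol Interactor B\t"
    "Synonyms Interactor A\tSynonyms Interactor B\tExperimental System\t"
    "Experimental System Type\tAuthor\tPubmed ID\tOrganism Interactor A\t"
    "Organism Interactor B\tThroughput\tScore\tModification\tPhenotypes\t"
    "Qualifications\tTags\tSource Database"
)


def _pick_identifier(systematic: str, symbol: str, line_no: int, path) -> str:
    systematic = systematic.strip()
    symbol = symbol.strip()
    if systematic and systematic != "-":
        return systematic
    if symbol and symbol != "-":
        return symbol
    raise ParseError(f"{path}:{line_no}: no usable interactor identifier")


def read_biogrid_tab2(
    path: str | Path, keep: str | InteractionClass | None = InteractionClass.PHYSICAL
) -> list[InteractionRecord]:
    """Read a BioGrid TAB 2.0 file, keeping rows of one experimental class.

    ``keep=None`` keeps every row.  The reader is non-lossy: it never
    deduplicates pairs — that is the network builder's job.
    """
    if isinstance(keep, str):
        keep = InteractionClass(keep)
    path = Path(path)
    records: list[InteractionRecord] = []
    n_data = 0
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < TAB2_MIN_COLUMNS:
                raise ParseError(
                    f"{path}:{line_no}: expected >= {TAB2_MIN_COLUMNS} tab-separated "
                    f"columns, got {len(cols)}"
                )
            n_data += 1
            cls_raw = cols[12].strip().lower()
            if cls_raw in ("physical", "genetic"):
                icls = InteractionClass(cls_raw)
            else:
                icls = InteractionClass.OTHER
            if keep is not None and icls is not keep:
                continue
            a = _pick_identifier(cols[5], cols[7], line_no, path)
            b = _pick_identifier(cols[6], cols[8], line_no, path)
            records.append(InteractionRecord(a, b, icls, line_no))
    if n_data == 0:
        raise ParseError(f"{path}: no interaction rows found")
    return records


def write_biogrid_tab2(records: Iterable[InteractionRecord], path: str | Path) -> None:
    """Write records as a minimal (padded) TAB 2.0 file; used for fixtures."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_TAB2_HEADER + "\n")
        for i, rec in enumerate(records, start=1):
            cols = ["-"] * TAB2_MIN_COLUMNS
            cols[0] = str(i)
            cols[5] = rec.protein_a
            cols[6] = rec.protein_b
            cols[11] = "Synthetic Assay"
            cols[12] = rec.interaction_class.value
            cols[23] = "SYNTHETIC"
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GAF 2.x
# ---------------------------------------------------------------------------

_ASPECT_FIELDS = {"C": "component", "F": "function", "P": "process"}


def read_gaf(path: str | Path) -> dict[str, AnnotationSet]:
    """Read a GAF 2.x annotation file into protein -> :class:`AnnotationSet`.

    NOT-qualified rows are excluded; duplicate (protein, aspect, term) rows
    collapse; an unknown aspect code or malformed GO id is a parse error
    naming the line.  The DB Object Symbol column (3rd) is the protein key.
    """
    path = Path(path)
    terms: dict[str, dict[str, set]] = {}
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("!"):
            continue
        cols = raw.split("\t")
        if len(cols) < 15:
            raise ParseError(f"{path}:{line_no}: expected >= 15 GAF columns, got {len(cols)}")
        qualifier = cols[3].strip()
        if "NOT" in qualifier.split("|"):
            continue
        go_id = cols[4].strip()
        if not GO_ID_RE.match(go_id):
            raise ParseError(f"{path}:{line_no}: malformed GO id {go_id!r}")
        aspect = cols[8].strip()
        if aspect not in _ASPECT_FIELDS:
            raise ParseError(f"{path}:{line_no}: unknown aspect code {aspect!r}")
        protein = cols[2].strip()
        if not protein:
            raise ParseError(f"{path}:{line_no}: empty DB object symbol")
        terms.setdefault(protein, {"C": set(), "F": set(), "P": set()})[aspect].add(go_id)
    return {
        p: AnnotationSet(frozenset(d["C"]), frozenset(d["F"]), frozenset(d["P"]))
        for p, d in terms.items()
    }


def write_gaf(annotations: Mapping[str, AnnotationSet], path: str | Path, taxon: str = "taxon:4932") -> None:
    """Write protein -> AnnotationSet as a GAF 2.2 file (fixture writer)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for protein in sorted(annotations):
            ann = annotations[protein]
            for aspect, terms in (("C", ann.component_terms), ("F", ann.function_terms), ("P", ann.process_terms)):
                for term in sorted(terms):
                    cols = [
                        "SPANET", protein, protein, "", term, "SPANET:0000001", "IEA",
                        "", aspect, "", "", "protein", taxon, "20240101", "SPANET", "", "",
                    ]
                    fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Networks (SIF and edge TSV)
# ---------------------------------------------------------------------------


def write_network(network: nx.Graph, path: str | Path, format: str = "edge_tsv") -> None:
    """Write an undirected network; each edge once, endpoints in lexicographic order.

    ``sif`` uses the Cytoscape dialect ``A pp B`` (isolated nodes on a line of
    their own); ``edge_tsv`` is two tab-separated columns.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network")
    path = Path(path)
    edges = sorted(tuple(sorted(e)) for e in network.edges())
    isolated = sorted(n for n in network.nodes() if network.degree(n) == 0)
    with path.open("w") as fh:
        if format == "sif":
            for a, b in edges:
                fh.write(f"{a}\tpp\t{b}\n")
            for n in isolated:
                fh.write(f"{n}\n")
        elif format == "edge_tsv":
            for a, b in edges:
                fh.write(f"{a}\t{b}\n")
            for n in isolated:
                fh.write(f"{n}\n")
        else:
            raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "edge_tsv") -> nx.Graph:
    """Read a network written by :func:`write_network` (either dialect)."""
    path = Path(path)
    graph = nx.Graph()
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if format == "sif":
            if len(cols) == 1:
                graph.add_node(cols[0].strip())
            elif len(cols) >= 3:
                graph.add_edge(cols[0].strip(), cols[2].strip())
            else:
                raise ParseError(f"{path}:{line_no}: malformed SIF line")
        else:
            if len(cols) == 1:
                graph.add_node(cols[0].strip())
            else:
                graph.add_edge(cols[0].strip(), cols[1].strip())
    return graph


# ---------------------------------------------------------------------------
# Simple column formats
# ---------------------------------------------------------------------------


def read_id_list(path: str | Path) -> list[str]:
    """Newline-delimited identifiers; blank lines and '#' comments skipped."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_regnet(path: str | Path) -> list[tuple[str, str]]:
    """TF -> target edge TSV (two columns, optional '#' header)."""
    edges = []
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) < 2:
            raise ParseError(f"{path}:{line_no}: expected 'tf<TAB>target'")
        edges.append((cols[0].strip(), cols[1].strip()))
    return edges


def read_pvalues(path: str | Path) -> dict[str, float]:
    """Gene -> p-value TSV (two columns, optional '#' header)."""
    out: dict[str, float] = {}
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) < 2:
            raise ParseError(f"{path}:{line_no}: expected 'gene<TAB>p'")
        try:
            p = float(cols[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{line_no}: bad p-value {cols[1]!r}") from exc
        out[cols[0].strip()] = p
    return out


def write_tsv(path: str | Path, header: list[str], rows: Iterable[Iterable]) -> None:
    """Write a TSV report table with a '#'-prefixed header row."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _fmt(value) -> str:
    if isinstance(value, float):
        return format(value, ".10g")
    if isinstance(value, bool):
        return "1" if value else "0"
    return str(value)
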