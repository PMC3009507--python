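"""Readers and writers for the standard file formats the tool touches.

Formats: OBO 1.2 ontologies (via obonet), GAF 2.x annotation files,
pfam2go-style mapping text, whitespace/TSV edge lists, and one-module-
per-line TSV module lists.  All text is UTF-8; CRLF line endings are
tolerated.
"""

from __future__ import annotations

import io
import logging
from typing import IO, Iterable, TextIO

import obonet

from .network import InteractionGraph
from .ontology import AnnotationCorpus, OntologyDAG

logger = logging.getLogger(__name__)

__all__ = [
    "parse_obo",
    "parse_gaf",
    "parse_mapping",
    "read_edgelist",
    "read_modules",
    "write_obo",
    "write_gaf",
    "write_edgelist",
    "write_modules",
]

#: Edge relations ingested from OBO; everything else (regulates, ...) is ignored.
_OBO_RELATIONS = frozenset({"is_a", "part_of"})

_ASPECT_BY_NAMESPACE = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}
_NAMESPACE_BY_ASPECT = {v: k for k, v in _ASPECT_BY_NAMESPACE.items()}


def _ensure_stream(source) -> TextIO:
    if isinstance(source, str):
        return open(source, encoding="utf-8")
    return source


def parse_obo(source: str | IO) -> dict[str, OntologyDAG]:
    """Parse an OBO 1.2 document into one DAG per namespace.

    ``is_a`` and ``part_of`` relationships are collapsed into a single
    edge kind; obsolete terms are skipped.  Terms without an explicit
    namespace go into the ``"default"`` namespace.  Each namespace must
    form an acyclic graph with a single root.
    """
    graph = obonet.read_obo(_ensure_stream(source), ignore_obsolete=True)
    by_ns: dict[str, dict] = {}
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace", "default")
        entry = by_ns.setdefault(ns, {"terms": set(), "edges": []})
        entry["terms"].add(term)
    for child, parent, key in graph.edges(keys=True):
        if key not in _OBO_RELATIONS:
            continue
        ns = graph.nodes[child].get("namespace", "default")
        if graph.nodes[parent].get("namespace", "default") != ns:
            continue  # cross-namespace links are outside the partial order
        by_ns[ns]["edges"].append((child, parent))
    return {
        ns: OntologyDAG(entry["edges"], terms=entry["terms"])
        for ns, entry in by_ns.items()
    }


def parse_gaf(
    source: str | IO,
    ontology: OntologyDAG,
    aspect: str | None = None,
    evidence_codes: Iterable[str] | None = None,
    lenient: bool = False,
) -> AnnotationCorpus:
    """Parse a GAF 2.x annotation file into a corpus over ``ontology``.

    Comment lines (``!``) are ignored; rows with a ``NOT`` qualifier are
    dropped.  ``aspect`` restricts to one sub-ontology ("P", "F" or "C");
    ``evidence_codes`` optionally whitelists evidence (off by default).
    Malformed rows (fewer than 15 tab-separated columns) raise a
    line-numbered error unless ``lenient`` is set, in which case they are
    skipped with a warning.  Terms unknown to the ontology are dropped by
    the corpus with a logged warning.
    """
    allowed = set(evidence_codes) if evidence_codes is not None else None
    annotations: dict[str, set[str]] = {}
    stream = _ensure_stream(source)
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\r\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            msg = f"line {lineno}: expected >= 15 GAF columns, got {len(cols)}"
            if lenient:
                logger.warning("skipping malformed GAF row: %s", msg)
                continue
            raise ValueError(msg)
        qualifier, go_id, evidence, row_aspect = cols[3], cols[4], cols[6], cols[8]
        if "NOT" in qualifier.split("|"):
            continue
        if aspect is not None and row_aspect != aspect:
            continue
        if allowed is not None and evidence not in allowed:
            continue
        annotations.setdefault(cols[1], set()).add(go_id)
    return AnnotationCorpus(ontology, annotations)


def parse_mapping(source: str | IO, ontology: OntologyDAG) -> AnnotationCorpus:
    """Parse a pfam2go-style mapping into a corpus.

    Accepts both the classic format ``Pfam:PF00001 entry > GO:label ;
    GO:0000001`` and plain two-column TSV ``entry<TAB>TERM``.  Duplicate
    associations collapse; lines mapping to terms unknown to the ontology
    (e.g. obsolete) are skipped and counted on the returned corpus.
    """
    annotations: dict[str, set[str]] = {}
    stream = _ensure_stream(source)
    for line in stream:
        line = line.rstrip("\r\n")
        if not line or line.startswith("!"):
            continue
        if ">" in line and ";" in line:
            head, _, tail = line.partition(">")
            entry = head.split()[0]
            if ":" in entry:  # "Pfam:PF00001 28" -> PF00001
                entry = entry.split(":", 1)[1]
            term = tail.rsplit(";", 1)[1].strip()
        else:
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                continue
            entry, term = parts[0], parts[1]
        annotations.setdefault(entry, set()).add(term)
    return AnnotationCorpus(ontology, annotations)


def read_edgelist(source: str | IO) -> InteractionGraph:
    """Read a whitespace/TSV edge list ``nodeA nodeB [weight]``.

    Undirected; duplicate edges are merged by summing weights; lines
    starting with ``#`` are comments.
    """
    edges: list[tuple[str, str, float]] = []
    stream = _ensure_stream(source)
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"edge line needs at least two columns: {line!r}")
        w = float(parts[2]) if len(parts) > 2 else 1.0
        edges.append((parts[0], parts[1], w))
    return InteractionGraph(edges)


def read_modules(source: str | IO) -> list[tuple[str, list[str]]]:
    """Read a module TSV: one module per line, first column the module
    identifier, remaining columns molecule identifiers."""
    modules: list[tuple[str, list[str]]] = []
    stream = _ensure_stream(source)
    for line in stream:
        line = line.rstrip("\r\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise ValueError(f"module line needs an id and at least one molecule: {line!r}")
        modules.append((cols[0], cols[1:]))
    return modules


# -- writers -------------------------------------------------------------------


def write_obo(ontology: OntologyDAG, stream: TextIO, namespace: str = "default") -> None:
    """Write a minimal OBO 1.2 document (is_a edges only)."""
    stream.write("format-version: 1.2\n")
    for term in sorted(ontology.terms):
        stream.write(f"\n[Term]\nid: {term}\nname: {term}\nnamespace: {namespace}\n")
        for parent in sorted(ontology.graph.successors(term)):
            stream.write(f"is_a: {parent}\n")


def write_gaf(corpus: AnnotationCorpus, stream: TextIO, aspect: str = "P") -> None:
    """Write the corpus's most-specific annotations as GAF 2.2 rows."""
    stream.write("!gaf-version: 2.2\n")
    for mol, tset in sorted(corpus.items()):
        for term in sorted(tset):
            cols = [
                "FC", mol, mol, "enables" if aspect == "F" else "involved_in",
                term, "FC:0000001", "IEA", "", aspect, mol, "", "protein",
                "taxon:0", "20100101", "FC", "", "",
            ]
            stream.write("\t".join(cols) + "\n")


def write_edgelist(graph: InteractionGraph, stream: TextIO) -> None:
    for u, v, data in sorted(graph.graph.edges(data=True)):
        stream.write(f"{u}\t{v}\t{data.get('weight', 1.0):g}\n")


def write_modules(modules: Iterable[tuple[str, Iterable[str]]], stream: TextIO) -> None:
    for mid, mols in modules:
        stream.write("\t".join([mid, *mols]) + "\n")
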