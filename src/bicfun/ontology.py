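"""Gene Ontology handling: OBO parsing, typed-edge DAG queries, annotation propagation.

Only ``is_a`` and ``part_of`` edges participate in transitive closure by
default; regulates-family edges are parsed and stored but excluded unless
explicitly requested.  The biological_process namespace is retained by
default.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: Relation kinds that define the transitive "transition-enabled" term tree.
CLOSURE_RELATIONS = frozenset({"is_a", "part_of"})

#: Relation kinds recognised on ``relationship:`` lines (others are kept verbatim).
KNOWN_RELATIONS = frozenset(
    {"is_a", "part_of", "regulates", "positively_regulates", "negatively_regulates"}
)


class OboParseError(ValueError):
    """Raised for malformed OBO input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class OntologyValidationError(ValueError):
    """Raised when the parsed term graph violates DAG invariants."""


@dataclass(frozen=True)
class Term:
    id: str
    name: str = ""
    namespace: str = ""


class OntologyDag:
    """Acyclic term graph with typed child-to-parent edges.

    Edges point from child to parent, so "ancestors" of a term are the
    nodes reachable by following edges forward.
    """

    def __init__(
        self,
        terms: Mapping[str, Term],
        edges: Iterable[tuple[str, str, str]],
        alt_ids: Mapping[str, str] | None = None,
        namespace: str | None = "biological_process",
    ):
        self._terms = dict(terms)
        self._alt_ids = dict(alt_ids or {})
        self.namespace = namespace
        g = nx.MultiDiGraph()
        g.add_nodes_from(self._terms)
        dropped = 0
        for child, parent, relation in edges:
            if child not in self._terms or parent not in self._terms:
                dropped += 1
                continue
            g.add_edge(child, parent, key=relation, relation=relation)
        if dropped:
            logger.warning("dropped %d edges with unregistered endpoints", dropped)
        self._graph = g
        self._restricted_cache: dict[frozenset[str], nx.DiGraph] = {}
        closure = self._restricted(CLOSURE_RELATIONS)
        if not nx.is_directed_acyclic_graph(closure):
            cycle = nx.find_cycle(closure)
            raise OntologyValidationError(f"cycle among is_a/part_of edges: {cycle}")
        full = self._restricted(frozenset(r for _, _, r in g.edges(keys=True)))
        if not nx.is_directed_acyclic_graph(full):
            raise OntologyValidationError("term graph contains a directed cycle")

    # -- basic container protocol -------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self):
        return iter(self._terms)

    @property
    def terms(self) -> Mapping[str, Term]:
        return self._terms

    @property
    def graph(self) -> nx.MultiDiGraph:
        return self._graph

    def resolve(self, term_id: str) -> str | None:
        """Map a (possibly alternate) id to its primary id, or None."""
        if term_id in self._terms:
            return term_id
        return self._alt_ids.get(term_id)

    def edges(self) -> list[tuple[str, str, str]]:
        return [(c, p, r) for c, p, r in self._graph.edges(keys=True)]

    # -- closure queries ----------------------------------------------------------
    def _restricted(self, relations: frozenset[str]) -> nx.DiGraph:
        key = frozenset(relations)
        cached = self._restricted_cache.get(key)
        if cached is None:
            cached = nx.DiGraph()
            cached.add_nodes_from(self._graph.nodes)
            for c, p, r in self._graph.edges(keys=True):
                if r in key:
                    cached.add_edge(c, p)
            self._restricted_cache[key] = cached
        return cached

    def _check(self, term_id: str) -> None:
        if term_id not in self._terms:
            raise KeyError(f"unknown term id: {term_id!r}")

    def parents(self, term_id: str, relations: Iterable[str] = CLOSURE_RELATIONS) -> set[str]:
        self._check(term_id)
        return set(self._restricted(frozenset(relations)).successors(term_id))

    def children(self, term_id: str, relations: Iterable[str] = CLOSURE_RELATIONS) -> set[str]:
        self._check(term_id)
        return set(self._restricted(frozenset(relations)).predecessors(term_id))

    def ancestors(self, term_id: str, relations: Iterable[str] = CLOSURE_RELATIONS) -> set[str]:
        """All terms reachable from ``term_id`` along edges of the given kinds."""
        self._check(term_id)
        return nx.descendants(self._restricted(frozenset(relations)), term_id)

    def descendants(self, term_id: str, relations: Iterable[str] = CLOSURE_RELATIONS) -> set[str]:
        """All terms from which ``term_id`` is reachable along the given kinds."""
        self._check(term_id)
        return nx.ancestors(self._restricted(frozenset(relations)), term_id)


# convenience module-level wrappers mirroring the method interface
def ancestors(dag: OntologyDag, term_id: str, relations: Iterable[str] = CLOSURE_RELATIONS) -> set[str]:
    return dag.ancestors(term_id, relations)


def descendants(dag: OntologyDag, term_id: str, relations: Iterable[str] = CLOSURE_RELATIONS) -> set[str]:
    return dag.descendants(term_id, relations)


def parse_obo(source, namespace: str | None = "biological_process") -> OntologyDag:
    """Parse OBO 1.2/1.4 flat-file text into an :class:`OntologyDag`.

    ``source`` may be a string, a text stream, or a path-like.  Non-obsolete
    ``[Term]`` stanzas of the configured namespace are kept (``namespace=None``
    keeps all); ``is_a`` and ``relationship`` lines become typed edges;
    ``alt_id`` lines are recorded and resolved to the primary id.
    """
    if hasattr(source, "read"):
        stream = source
    elif isinstance(source, str) and "\n" in source:
        stream = io.StringIO(source)
    else:
        stream = open(source, "r", encoding="utf-8")

    default_namespace = ""
    terms: dict[str, Term] = {}
    edges: list[tuple[str, str, str]] = []
    alt_ids: dict[str, str] = {}
    obsolete: set[str] = set()
    term_ns: dict[str, str] = {}

    in_header = True
    stanza: dict | None = None
    stanza_type = ""

    def flush(lineno: int) -> None:
        nonlocal stanza
        if stanza is None or stanza_type != "Term":
            stanza = None
            return
        tid = stanza.get("id")
        if tid is None:
            raise OboParseError("[Term] stanza without an id", lineno)
        if stanza.get("is_obsolete"):
            obsolete.add(tid)
            stanza = None
            return
        if tid in terms:
            raise OboParseError(f"duplicate term id {tid}", lineno)
        terms[tid] = Term(tid, stanza.get("name", ""), stanza.get("namespace", ""))
        term_ns[tid] = stanza.get("namespace", "")
        for parent, rel in stanza.get("edges", []):
            edges.append((tid, parent, rel))
        for alt in stanza.get("alt_ids", []):
            alt_ids[alt] = tid
        stanza = None

    lineno = 0
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                flush(lineno)
                in_header = False
                stanza_type = line[1:-1]
                stanza = {"edges": [], "alt_ids": []}
                continue
            if ":" not in line:
                raise OboParseError(f"expected 'tag: value', got {line!r}", lineno)
            tag, _, value = line.partition(":")
            tag, value = tag.strip(), value.strip()
            if in_header:
                if tag == "default-namespace":
                    default_namespace = value
                continue
            if stanza is None or stanza_type != "Term":
                continue
            if tag == "id":
                stanza["id"] = value
            elif tag == "name":
                stanza["name"] = value
            elif tag == "namespace":
                stanza["namespace"] = value
            elif tag == "is_obsolete":
                stanza["is_obsolete"] = value.lower() == "true"
            elif tag == "is_a":
                if not value:
                    raise OboParseError("is_a without a target term", lineno)
                stanza["edges"].append((value.split()[0], "is_a"))
            elif tag == "relationship":
                parts = value.split()
                if len(parts) < 2:
                    raise OboParseError(f"malformed relationship line: {value!r}", lineno)
                stanza["edges"].append((parts[1], parts[0]))
            elif tag == "alt_id":
                stanza["alt_ids"].append(value)
        flush(lineno + 1)
    finally:
        if stream is not source:
            stream.close()

    # namespace filtering: a term with no namespace line inherits the header default
    if namespace is not None:
        keep = {tid for tid in terms if (term_ns[tid] or default_namespace) in ("", namespace)}
        terms = {tid: t for tid, t in terms.items() if tid in keep}
        alt_ids = {a: p for a, p in alt_ids.items() if p in keep}
    edges = [e for e in edges if e[0] in terms and e[1] in terms and e[1] not in obsolete]
    # an alt_id colliding with a primary id resolves to the primary term
    alt_ids = {a: p for a, p in alt_ids.items() if a not in terms}
    return OntologyDag(terms, edges, alt_ids, namespace=namespace)


def write_obo(dag: OntologyDag, path) -> None:
    """Write the DAG back out as a minimal OBO 1.2 flat file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        if dag.namespace:
            fh.write(f"default-namespace: {dag.namespace}\n")
        outgoing: dict[str, list[tuple[str, str]]] = {}
        for c, p, r in dag.edges():
            outgoing.setdefault(c, []).append((p, r))
        for tid in sorted(dag.terms):
            term = dag.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\n")
            if term.name:
                fh.write(f"name: {term.name}\n")
            if term.namespace:
                fh.write(f"namespace: {term.namespace}\n")
            for parent, rel in sorted(outgoing.get(tid, [])):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


@dataclass(frozen=True)
class TermAnnotation:
    """Gene-to-term annotation map with a propagation flag."""

    mapping: Mapping[str, frozenset[str]]
    propagated: bool = False

    def genes(self) -> set[str]:
        return set(self.mapping)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.mapping.get(gene, frozenset())

    def __len__(self) -> int:
        return len(self.mapping)


def read_annotation_tsv(path) -> TermAnnotation:
    """Read a two-column ``gene<TAB>term`` file (one pair per line)."""
    mapping: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected two tab-separated columns")
            gene, term = parts
            mapping.setdefault(gene, set()).add(term)
    return TermAnnotation({g: frozenset(t) for g, t in mapping.items()})


def read_gaf(path) -> TermAnnotation:
    """Read a GAF 2.1/2.2 file using columns 2 (symbol) and 5 (GO id)."""
    mapping: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("!"):
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 5:
                raise ValueError("GAF line with fewer than 5 columns")
            mapping.setdefault(cols[1], set()).add(cols[4])
    return TermAnnotation({g: frozenset(t) for g, t in mapping.items()})


def write_annotation_tsv(annot: TermAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(annot.mapping):
            for term in sorted(annot.mapping[gene]):
                fh.write(f"{gene}\t{term}\n")


def propagate_annotations(
    dag: OntologyDag,
    annot: TermAnnotation,
    relations: Iterable[str] = CLOSURE_RELATIONS,
) -> TermAnnotation:
    """Apply the true-path rule: each gene inherits all ancestors of its terms.

    Records referencing unknown terms (after alt_id resolution) are dropped
    with a logged count.  Idempotent; annotation sets only grow.
    """
    if annot.propagated:
        return annot
    relations = frozenset(relations)
    closure_cache: dict[str, set[str]] = {}
    dropped = 0
    new_mapping: dict[str, frozenset[str]] = {}
    for gene, terms in annot.mapping.items():
        expanded: set[str] = set()
        for term in terms:
            primary = dag.resolve(term)
            if primary is None:
                dropped += 1
                continue
            if primary not in closure_cache:
                closure_cache[primary] = {primary} | dag.ancestors(primary, relations)
            expanded |= closure_cache[primary]
        if expanded:
            new_mapping[gene] = frozenset(expanded)
    if dropped:
        logger.warning("propagate_annotations: dropped %d records with unknown terms", dropped)
    return TermAnnotation(new_mapping, propagated=True)
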