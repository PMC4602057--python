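"""Reading and writing ontologies in the OBO 1.2 flat-file format.

The parser covers the tag subset needed for term-enrichment work:
``id``, ``name``, ``namespace``, ``alt_id``, ``is_a``,
``relationship: <rel> <id>`` and ``is_obsolete`` inside ``[Term]``
stanzas, plus the ``format-version`` / ``default-namespace`` header
tags. Unknown tags and non-Term stanzas (e.g. ``[Typedef]``) are
ignored with a debug log line. Obsolete terms are retained for
identifier resolution but carry no edges and never take part in
analysis or display.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

import networkx as nx

from .errors import OboParseError, OntologyValidationError

logger = logging.getLogger(__name__)


class Relation(str, enum.Enum):
    """Typed parent-child relations recognized in the ontology graph."""

    IS_A = "is_a"
    PART_OF = "part_of"
    POSITIVELY_REGULATES = "positively_regulates"
    NEGATIVELY_REGULATES = "negatively_regulates"
    REGULATES = "regulates"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Relations propagated by default under the true-path rule.
DEFAULT_PROPAGATION = frozenset({Relation.IS_A, Relation.PART_OF})


@dataclass
class Term:
    """One ontology term (a node of the DAG)."""

    id: str
    name: str = ""
    namespace: str = "default"
    is_obsolete: bool = False
    alt_ids: set[str] = field(default_factory=set)


@dataclass
class Ontology:
    """A multi-namespace ontology: terms, typed edges and per-namespace roots.

    ``edges`` holds ``(child_id, parent_id, relation)`` triples; the child
    is the more specific term. ``roots`` maps each namespace to its single
    root term (the term with no outgoing edges).
    """

    terms: dict[str, Term] = field(default_factory=dict)
    edges: set[tuple[str, str, Relation]] = field(default_factory=set)
    roots: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._alt_map: dict[str, str] | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return (
            self.terms == other.terms
            and self.edges == other.edges
            and self.roots == other.roots
        )

    def graph(self, relations: Optional[Iterable[Relation]] = None) -> nx.DiGraph:
        """Child-to-parent digraph restricted to ``relations`` (default: all).

        Parallel edges of different relation types collapse to one arc;
        use :attr:`edges` when the relation type matters.
        """
        wanted = set(relations) if relations is not None else set(Relation)
        g = nx.DiGraph()
        g.add_nodes_from(
            t.id for t in self.terms.values() if not t.is_obsolete
        )
        g.add_edges_from(
            (c, p) for (c, p, r) in self.edges if r in wanted
        )
        return g

    def parents(self, term_id: str) -> list[tuple[str, Relation]]:
        return sorted(
            (p, r) for (c, p, r) in self.edges if c == term_id
        )

    @property
    def alt_map(self) -> dict[str, str]:
        if self._alt_map is None:
            self._alt_map = {
                alt: t.id for t in self.terms.values() for alt in t.alt_ids
            }
        return self._alt_map


_BOOL_TRUE = {"true", "1"}


def _strip_comment(value: str) -> str:
    # `is_a: GO:0008150 ! biological_process` -- drop the trailing label
    idx = value.find(" ! ")
    if idx >= 0:
        value = value[:idx]
    elif value.endswith("!"):
        value = value[:-1]
    return value.strip()


def parse_obo(stream: IO[str]) -> Ontology:
    """Parse an OBO 1.2 document into an :class:`Ontology`.

    Raises
    ------
    OboParseError
        for a ``[Term]`` stanza without an ``id`` line (the error names
        the line where the stanza starts).
    OntologyValidationError
        if the edge graph contains a directed cycle (one cycle is named).
    """
    default_namespace: str | None = None
    stanzas: list[dict] = []
    current: dict | None = None  # None => header or ignored stanza
    in_header = True

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("["):
            in_header = False
            if stripped == "[Term]":
                current = {
                    "line": lineno,
                    "id": None,
                    "name": "",
                    "namespace": None,
                    "alt_ids": set(),
                    "obsolete": False,
                    "links": [],  # (relation string, target, lineno)
                }
                stanzas.append(current)
            else:
                logger.debug("ignoring stanza %s at line %d", stripped, lineno)
                current = None
            continue
        if ":" not in stripped:
            logger.debug("ignoring malformed line %d: %r", lineno, stripped)
            continue
        tag, _, value = stripped.partition(":")
        tag = tag.strip()
        value = value.strip()
        if in_header:
            if tag == "default-namespace":
                default_namespace = value
            elif tag != "format-version":
                logger.debug("ignoring header tag %r (line %d)", tag, lineno)
            continue
        if current is None:
            continue
        if tag == "id":
            current["id"] = _strip_comment(value)
        elif tag == "name":
            current["name"] = value
        elif tag == "namespace":
            current["namespace"] = value
        elif tag == "alt_id":
            current["alt_ids"].add(_strip_comment(value))
        elif tag == "is_a":
            current["links"].append((Relation.IS_A.value, _strip_comment(value), lineno))
        elif tag == "relationship":
            parts = _strip_comment(value).split()
            if len(parts) != 2:
                raise OboParseError(
                    f"cannot parse relationship line: {stripped!r}", line=lineno
                )
            current["links"].append((parts[0], parts[1], lineno))
        elif tag == "is_obsolete":
            current["obsolete"] = value.lower() in _BOOL_TRUE
        else:
            logger.debug("ignoring tag %r in [Term] (line %d)", tag, lineno)

    ontology = Ontology()
    fallback_ns = default_namespace or "default"
    pending: list[tuple[str, str, str, int]] = []
    for st in stanzas:
        if not st["id"]:
            raise OboParseError("[Term] stanza has no id", line=st["line"])
        tid = st["id"]
        if tid in ontology.terms:
            raise OboParseError(f"duplicate term id {tid!r}", line=st["line"])
        ontology.terms[tid] = Term(
            id=tid,
            name=st["name"],
            namespace=st["namespace"] or fallback_ns,
            is_obsolete=st["obsolete"],
            alt_ids=st["alt_ids"],
        )
        for rel, target, lineno in st["links"]:
            pending.append((tid, rel, target, lineno))

    # alt_ids must stay disjoint from primary ids
    for term in ontology.terms.values():
        clash = term.alt_ids & ontology.terms.keys()
        if clash:
            logger.warning(
                "term %s lists primary id(s) %s as alt_id; dropping",
                term.id,
                ",".join(sorted(clash)),
            )
            term.alt_ids -= clash

    known_relations = {r.value: r for r in Relation}
    for child, rel, target, lineno in pending:
        if rel not in known_relations:
            logger.debug(
                "ignoring relationship %r at line %d (unsupported type)", rel, lineno
            )
            continue
        if ontology.terms[child].is_obsolete:
            logger.warning(
                "dropping edge from obsolete term %s (line %d)", child, lineno
            )
            continue
        parent = ontology.terms.get(target)
        if parent is None or parent.is_obsolete:
            logger.warning(
                "dropping edge %s -> %s (line %d): parent %s",
                child,
                target,
                lineno,
                "missing" if parent is None else "obsolete",
            )
            continue
        ontology.edges.add((child, target, known_relations[rel]))

    _validate_acyclic(ontology)
    ontology.roots = _find_roots(ontology)
    return ontology


def _validate_acyclic(ontology: Ontology) -> None:
    g = ontology.graph()
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return
    path = " -> ".join([cycle[0][0]] + [edge[1] for edge in cycle])
    raise OntologyValidationError(f"ontology contains a cycle: {path}")


def _find_roots(ontology: Ontology) -> dict[str, str]:
    """One root per namespace: the parentless term with the most descendants."""
    has_parent = {c for (c, _p, _r) in ontology.edges}
    g = ontology.graph()
    roots: dict[str, str] = {}
    by_ns: dict[str, list[str]] = {}
    for term in ontology.terms.values():
        if term.is_obsolete or term.id in has_parent:
            continue
        by_ns.setdefault(term.namespace, []).append(term.id)
    for ns, candidates in by_ns.items():
        if len(candidates) > 1:
            # prefer the candidate dominating the namespace; warn about strays
            candidates.sort(
                key=lambda t: (-len(nx.ancestors(g, t)), t)
            )
            logger.warning(
                "namespace %r has %d parentless terms; using %s as root",
                ns,
                len(candidates),
                candidates[0],
            )
        roots[ns] = candidates[0] if candidates else ""
        if not candidates:
            del roots[ns]
    return roots


def write_obo(ontology: Ontology, stream: IO[str]) -> None:
    """Serialize ``ontology`` so that :func:`parse_obo` round-trips it.

    Terms are emitted sorted by id with tags in canonical order; a
    ``default-namespace`` header is written when all terms share one
    namespace.
    """
    stream.write("format-version: 1.2\n")
    namespaces = {t.namespace for t in ontology.terms.values()}
    if len(namespaces) == 1:
        stream.write(f"default-namespace: {next(iter(namespaces))}\n")
    edges_by_child: dict[str, list[tuple[str, Relation]]] = {}
    for child, parent, rel in ontology.edges:
        edges_by_child.setdefault(child, []).append((parent, rel))
    for tid in sorted(ontology.terms):
        term = ontology.terms[tid]
        stream.write("\n[Term]\n")
        stream.write(f"id: {term.id}\n")
        if term.name:
            stream.write(f"name: {term.name}\n")
        stream.write(f"namespace: {term.namespace}\n")
        for alt in sorted(term.alt_ids):
            stream.write(f"alt_id: {alt}\n")
        if term.is_obsolete:
            stream.write("is_obsolete: true\n")
        for parent, rel in sorted(edges_by_child.get(tid, []), key=lambda e: (e[0], e[1].value)):
            if rel is Relation.IS_A:
                stream.write(f"is_a: {parent}\n")
            else:
                stream.write(f"relationship: {rel.value} {parent}\n")


def resolve_term(ontology: Ontology, accession: str) -> Optional[str]:
    """Map an accession (primary or alt_id) to its primary term id.

    Returns ``None`` for unknown accessions. Obsolete primary ids resolve
    to themselves; callers decide whether obsolete terms are acceptable.
    """
    if accession in ontology.terms:
        return accession
    return ontology.alt_map.get(accession)
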