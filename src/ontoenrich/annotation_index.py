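"""Closure of annotations over the ontology (the true-path rule).

A gene directly annotated to a term is implicitly annotated to every
ancestor of that term reachable through the propagation relations
(``is_a`` and ``part_of`` by default). The resulting per-term closed
gene sets supply the K (term closure size) and N (universe size)
counts of the hypergeometric test.

The universe policy is per-namespace by default: each namespace root
defines its own background of genes carrying at least one annotation in
that namespace. A pooled universe (single N across namespaces) is
available for callers who want the classic single-background behaviour.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

import networkx as nx

from .errors import AnnotationError, QueryError
from .gaf_io import AnnotationRecord
from .obo_io import DEFAULT_PROPAGATION, Ontology, Relation, resolve_term

logger = logging.getLogger(__name__)

#: Reason codes attached to unresolved query tokens.
REASON_UNKNOWN = "unknown-identifier"
REASON_OUTSIDE_UNIVERSE = "outside-universe"


@dataclass
class AnnotationIndex:
    """Per-term closed gene sets plus the analysis universe.

    ``closed_genes[t]`` is the set of genes annotated to ``t`` or any of
    its descendants (K_t = len of it); ``universe`` is the pooled
    background (N under the pooled policy); ``namespace_universe[ns]``
    is the per-namespace background. ``symbol_map`` maps lower-cased
    ids, symbols and synonyms to gene ids for query resolution.
    """

    closed_genes: dict[str, frozenset[str]]
    universe: frozenset[str]
    namespace_universe: dict[str, frozenset[str]]
    symbol_map: dict[str, str]
    gene_symbols: dict[str, str]
    term_names: dict[str, str]
    term_namespaces: dict[str, str]
    roots: dict[str, str]

    def closure(self, term_id: str) -> frozenset[str]:
        return self.closed_genes.get(term_id, frozenset())


@dataclass
class QuerySet:
    """A resolved query gene list with display metadata."""

    label: str
    color: str
    genes: frozenset[str]
    unresolved: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.genes)


def build_index(
    ontology: Ontology,
    records: Iterable[AnnotationRecord],
    universe: Optional[set[str]] = None,
    propagate_relations: Iterable[Relation] = DEFAULT_PROPAGATION,
    count_unannotated: bool = False,
) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from an ontology and GAF records.

    Records are dropped (with a summary warning) when their term id does
    not resolve, resolves to an obsolete term, or the annotation carries
    a NOT qualifier; alt_ids resolve to their primary term. When a
    custom ``universe`` is given, records for genes outside it are
    dropped and the background is restricted accordingly;
    ``count_unannotated=True`` keeps unannotated universe genes in the
    pooled N.

    Raises :class:`AnnotationError` when no record survives.
    """
    propagate = frozenset(propagate_relations)
    direct: dict[str, set[str]] = {}
    gene_symbols: dict[str, str] = {}
    synonym_candidates: dict[str, set[str]] = {}
    symbol_candidates: dict[str, set[str]] = {}
    seen_pairs: set[tuple[str, str]] = set()
    n_unresolved = n_obsolete = n_not = n_outside = n_used = 0

    for rec in records:
        if rec.is_negated:
            n_not += 1
            continue
        term_id = resolve_term(ontology, rec.term_id)
        if term_id is None:
            n_unresolved += 1
            continue
        if ontology.terms[term_id].is_obsolete:
            n_obsolete += 1
            continue
        if universe is not None and rec.gene_id not in universe:
            n_outside += 1
            continue
        n_used += 1
        if (rec.gene_id, term_id) not in seen_pairs:
            seen_pairs.add((rec.gene_id, term_id))
            direct.setdefault(term_id, set()).add(rec.gene_id)
        if rec.symbol:
            gene_symbols.setdefault(rec.gene_id, rec.symbol)
            symbol_candidates.setdefault(rec.symbol.lower(), set()).add(rec.gene_id)
        for syn in rec.synonyms:
            synonym_candidates.setdefault(syn.lower(), set()).add(rec.gene_id)

    for label, count in (
        ("unresolvable term ids", n_unresolved),
        ("obsolete terms", n_obsolete),
        ("NOT-qualified annotations", n_not),
        ("genes outside the custom universe", n_outside),
    ):
        if count:
            logger.warning("dropped %d records (%s)", count, label)
    if n_used == 0:
        raise AnnotationError("no usable annotations")

    closed = _propagate(ontology, direct, propagate)

    annotated = frozenset().union(*closed.values()) if closed else frozenset()
    if universe is not None and count_unannotated:
        pooled = frozenset(universe)
    else:
        pooled = annotated

    namespace_universe: dict[str, frozenset[str]] = {}
    for term_id, genes in closed.items():
        ns = ontology.terms[term_id].namespace
        namespace_universe[ns] = namespace_universe.get(ns, frozenset()) | genes

    # deterministic resolution map: ids shadow symbols shadow synonyms;
    # ambiguous symbols resolve to the smallest gene id (order independent)
    symbol_map: dict[str, str] = {}
    for key, cands in sorted(synonym_candidates.items()):
        symbol_map[key] = min(cands)
    for key, cands in sorted(symbol_candidates.items()):
        symbol_map[key] = min(cands)
    for gene in annotated:
        symbol_map[gene.lower()] = gene

    return AnnotationIndex(
        closed_genes={t: frozenset(g) for t, g in closed.items()},
        universe=pooled,
        namespace_universe=namespace_universe,
        symbol_map=symbol_map,
        gene_symbols=gene_symbols,
        term_names={t: ontology.terms[t].name for t in closed},
        term_namespaces={t: ontology.terms[t].namespace for t in closed},
        roots=dict(ontology.roots),
    )


def _propagate(
    ontology: Ontology,
    direct: dict[str, set[str]],
    relations: frozenset[Relation],
) -> dict[str, set[str]]:
    """Push direct annotations to all ancestors along ``relations`` edges."""
    g = ontology.graph(relations)
    closed: dict[str, set[str]] = {t: set(genes) for t, genes in direct.items()}
    # edges run child -> parent, so topological order visits children first
    for node in nx.topological_sort(g):
        genes = closed.get(node)
        if not genes:
            continue
        for parent in g.successors(node):
            closed.setdefault(parent, set()).update(genes)
    return {t: g for t, g in closed.items() if g}


def load_gene_list(stream: IO[str]) -> list[str]:
    """Read a gene-list file: one token per line, '#' comments, blanks skipped."""
    tokens = []
    for raw in stream:
        line = raw.split("#", 1)[0].strip()
        if line:
            tokens.append(line)
    return tokens


def resolve_query(
    tokens: Iterable[str],
    index: AnnotationIndex,
    label: str = "query",
    color: str = "#e6c229",
) -> QuerySet:
    """Resolve identifier tokens into a :class:`QuerySet`.

    Tokens match case-insensitively against gene ids, then symbols, then
    synonyms. Non-matching tokens and matches outside the universe land
    in ``unresolved`` with a reason code; analysis proceeds on the
    resolved genes. Raises :class:`QueryError` if nothing resolves.
    """
    genes: set[str] = set()
    unresolved: list[tuple[str, str]] = []
    any_token = False
    for token in tokens:
        token = token.strip()
        if not token or token.startswith("#"):
            continue
        any_token = True
        gene = index.symbol_map.get(token.lower())
        if gene is None:
            unresolved.append((token, REASON_UNKNOWN))
        elif gene not in index.universe:
            unresolved.append((token, REASON_OUTSIDE_UNIVERSE))
        else:
            genes.add(gene)
    if not any_token:
        raise QueryError(f"query set {label!r} contains no tokens")
    if not genes:
        raise QueryError(f"empty query after resolution for set {label!r}")
    return QuerySet(label=label, color=color, genes=frozenset(genes), unresolved=unresolved)
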