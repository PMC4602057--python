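"""Deterministic synthetic ontologies, annotation sets and query lists.

The generator builds a rooted random DAG (each new term attaches to one
or more earlier terms with relations drawn from a configurable mix),
annotates genes to random terms, and can plant an enrichment signal: a
designated term whose gene closure overlaps a generated query list by a
chosen amount. Everything is reproducible from the seed. These fixtures
emulate the combinatorial structure of ontology annotation data (DAG
topology, closure monotonicity, term-size variation) but not the
long-tailed term-size distribution or inter-term correlation of real
curated corpora.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .annotation_index import build_index
from .errors import FixtureError
from .gaf_io import AnnotationRecord, write_gaf
from .obo_io import DEFAULT_PROPAGATION, Ontology, Relation, Term, write_obo

_DEFAULT_MIX = {Relation.IS_A: 0.6, Relation.PART_OF: 0.25, Relation.REGULATES: 0.15}
_EVIDENCE_CODES = ("IDA", "ISS", "IEA")


@dataclass
class PlantedSignal:
    """Recipe for an enriched (or depleted) query against one term.

    ``closure_size`` (optional) forces the planted term to be a leaf with
    exactly that many annotated genes, so K is known in advance.
    ``overlap`` query genes are drawn from the closure, the rest from
    outside it; ``overlap=0`` yields a depletion fixture.
    """

    term_index: int
    query_size: int
    overlap: int
    closure_size: Optional[int] = None


@dataclass
class FixtureSpec:
    seed: int = 0
    n_terms: int = 30
    n_genes: int = 100
    max_parents: int = 3
    relation_mix: dict[Relation, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIX)
    )
    annotations_per_gene: float = 3.0
    n_namespaces: int = 1
    planted: Optional[PlantedSignal] = None

    def validate(self) -> None:
        if min(self.n_terms, self.n_genes, self.max_parents, self.n_namespaces) < 1:
            raise FixtureError("all fixture counts must be positive")
        if self.annotations_per_gene <= 0:
            raise FixtureError("annotations_per_gene must be positive")
        total = sum(self.relation_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise FixtureError(f"relation_mix proportions sum to {total}, not 1")
        if self.planted is not None:
            pl = self.planted
            if not 1 <= pl.term_index < self.n_terms:
                raise FixtureError(
                    "planted term_index must name a non-root term"
                )
            if pl.overlap > pl.query_size or pl.overlap < 0:
                raise FixtureError("planted overlap must lie in [0, query_size]")
            if self.n_namespaces != 1:
                raise FixtureError("planted signals require a single namespace")


def _term_id(i: int) -> str:
    return f"TST:{i:07d}"


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def generate(
    spec: FixtureSpec,
) -> tuple[Ontology, list[AnnotationRecord], Optional[list[str]]]:
    """Build (ontology, annotation records, query tokens or None) from a spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rels = sorted(spec.relation_mix, key=lambda r: r.value)
    rel_probs = np.array([spec.relation_mix[r] for r in rels], dtype=float)
    rel_probs /= rel_probs.sum()

    ontology = Ontology()
    # partition terms across namespaces; namespace j gets a contiguous block
    per_ns = [spec.n_terms // spec.n_namespaces] * spec.n_namespaces
    per_ns[0] += spec.n_terms - sum(per_ns)
    namespaces = (
        ["biological_process"]
        if spec.n_namespaces == 1
        else [f"namespace_{j}" for j in range(spec.n_namespaces)]
    )
    planted_id = (
        _term_id(spec.planted.term_index)
        if spec.planted is not None and spec.planted.closure_size is not None
        else None
    )

    idx = 0
    ns_members: dict[str, list[str]] = {}
    for ns, count in zip(namespaces, per_ns):
        members: list[str] = []
        for local in range(count):
            tid = _term_id(idx)
            ontology.terms[tid] = Term(
                id=tid, name=f"synthetic term {idx}", namespace=ns
            )
            if local > 0:
                # keep a forced-closure planted term childless (a leaf)
                candidates = [t for t in members if t != planted_id]
                if not candidates:
                    candidates = [members[0]]
                n_par = int(rng.integers(1, min(spec.max_parents, len(candidates)) + 1))
                parents = rng.choice(
                    np.array(candidates, dtype=object), size=n_par, replace=False
                )
                for pi, parent in enumerate(parents):
                    rel = rels[int(rng.choice(len(rels), p=rel_probs))]
                    if pi == 0 and rel not in DEFAULT_PROPAGATION:
                        # every term stays connected to its root through the
                        # propagating relations, as in curated ontologies
                        prop = [r for r in rels if r in DEFAULT_PROPAGATION]
                        rel = prop[0] if prop else rel
                    ontology.edges.add((tid, str(parent), rel))
            members.append(tid)
            idx += 1
        ontology.roots[ns] = members[0]
        ns_members[ns] = members

    genes = [_gene_id(i) for i in range(spec.n_genes)]
    records: list[AnnotationRecord] = []
    aspect_of = {ns: chr(ord("A") + j) for j, ns in enumerate(namespaces)}

    def make_record(gene_i: int, term: str, evidence: str) -> AnnotationRecord:
        ns = ontology.terms[term].namespace
        return AnnotationRecord(
            db="TEST",
            gene_id=genes[gene_i],
            symbol=f"Gene{gene_i}",
            qualifiers=frozenset(),
            term_id=term,
            evidence_code=evidence,
            aspect=aspect_of[ns],
            synonyms=frozenset({f"alias{gene_i}"}),
        )

    annotatable = [t for ns in namespaces for t in ns_members[ns] if t != planted_id]
    for gene_i in range(spec.n_genes):
        n_ann = max(1, int(rng.poisson(spec.annotations_per_gene)))
        terms = rng.choice(len(annotatable), size=min(n_ann, len(annotatable)), replace=False)
        for ti in sorted(terms):
            evidence = _EVIDENCE_CODES[int(rng.choice(len(_EVIDENCE_CODES)))]
            records.append(make_record(gene_i, annotatable[ti], evidence))

    query: Optional[list[str]] = None
    if spec.planted is not None:
        pl = spec.planted
        target = _term_id(pl.term_index)
        if pl.closure_size is not None:
            if pl.closure_size > spec.n_genes:
                raise FixtureError("closure_size exceeds the gene count")
            chosen = rng.choice(spec.n_genes, size=pl.closure_size, replace=False)
            for gene_i in sorted(chosen):
                records.append(make_record(int(gene_i), target, "IDA"))
        index = build_index(ontology, records)
        closure = sorted(index.closure(target))
        if pl.overlap > len(closure):
            raise FixtureError(
                f"planted overlap {pl.overlap} exceeds closure size {len(closure)}"
            )
        outside = sorted(set(genes) - set(closure))
        if pl.query_size - pl.overlap > len(outside):
            raise FixtureError("query_size exceeds available non-closure genes")
        inside_pick = rng.choice(len(closure), size=pl.overlap, replace=False)
        outside_pick = rng.choice(
            len(outside), size=pl.query_size - pl.overlap, replace=False
        )
        query = sorted(
            [closure[i] for i in inside_pick] + [outside[i] for i in outside_pick]
        )

    return ontology, records, query


def write_fixture(
    ontology: Ontology,
    records: list[AnnotationRecord],
    directory: Path,
    query_tokens: Optional[list[str]] = None,
) -> dict[str, Path]:
    """Write OBO/GAF/gene-list files consumable by the CLI; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": directory / "fixture.obo",
        "gaf": directory / "fixture.gaf",
    }
    with open(paths["obo"], "w", encoding="utf-8") as fh:
        write_obo(ontology, fh)
    with open(paths["gaf"], "w", encoding="utf-8") as fh:
        write_gaf(records, fh)
    if query_tokens is not None:
        paths["query"] = directory / "query.txt"
        paths["query"].write_text(
            "# synthetic query gene list\n" + "\n".join(query_tokens) + "\n",
            encoding="utf-8",
        )
    return paths
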