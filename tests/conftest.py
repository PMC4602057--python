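import io

import pytest

from ontoenrich.annotation_index import build_index
from ontoenrich.gaf_io import AnnotationRecord
from ontoenrich.obo_io import Ontology, Relation, Term, parse_obo

THREE_TERM_OBO = """\
format-version: 1.2
default-namespace: biological_process

[Term]
id: TST:0000000
name: root

[Term]
id: TST:0000001
name: alpha
is_a: TST:0000000 ! root

[Term]
id: TST:0000002
name: beta
relationship: part_of TST:0000000
"""


def make_record(gene, term, evidence="IDA", qualifiers=(), symbol=None, synonyms=()):
    return AnnotationRecord(
        db="TEST",
        gene_id=gene,
        symbol=symbol if symbol is not None else gene.lower(),
        qualifiers=frozenset(qualifiers),
        term_id=term,
        evidence_code=evidence,
        aspect="P",
        synonyms=frozenset(synonyms),
    )


@pytest.fixture
def three_term_ontology() -> Ontology:
    """Root R with children A (is_a) and B (part_of)."""
    return parse_obo(io.StringIO(THREE_TERM_OBO))


@pytest.fixture
def three_gene_records():
    """g1->A, g2->B, g3->A: closures A={g1,g3}, B={g2}, R=all three."""
    return [
        make_record("g1", "TST:0000001"),
        make_record("g2", "TST:0000002"),
        make_record("g3", "TST:0000001"),
    ]


@pytest.fixture
def small_index(three_term_ontology, three_gene_records):
    return build_index(three_term_ontology, three_gene_records)


R, A, B = "TST:0000000", "TST:0000001", "TST:0000002"


@pytest.fixture
def term_ids():
    return R, A, B


def chain_ontology() -> Ontology:
    """R <- X <- Y <- T, a 4-term is_a chain."""
    onto = Ontology()
    ids = ["TST:0000000", "TST:0000010", "TST:0000011", "TST:0000012"]
    for tid in ids:
        onto.terms[tid] = Term(id=tid, name=f"chain {tid}", namespace="biological_process")
    for child, parent in zip(ids[1:], ids[:-1]):
        onto.edges.add((child, parent, Relation.IS_A))
    onto.roots = {"biological_process": ids[0]}
    return onto
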