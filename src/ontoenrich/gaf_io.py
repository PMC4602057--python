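"""Reading gene-to-term association files in GAF format.

Both GAF 1.0 (15 columns) and GAF 2.x (17 columns) are accepted; the
version is detected per line from the column count rather than from a
``!gaf-version`` header, so hand-authored files without headers parse
too. Columns beyond 15 are ignored. Evidence codes are kept verbatim,
including user-defined codes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

from .errors import ConfigurationError, GafParseError

logger = logging.getLogger(__name__)

#: Mapping columns 1-11 of a GAF line (0-based indices).
_COL_DB = 0
_COL_GENE = 1
_COL_SYMBOL = 2
_COL_QUALIFIER = 3
_COL_TERM = 4
_COL_EVIDENCE = 6
_COL_ASPECT = 8
_COL_SYNONYM = 10
_MIN_COLUMNS = 15


@dataclass
class AnnotationRecord:
    """One GAF row: a gene annotated to an ontology term."""

    db: str
    gene_id: str
    symbol: str
    qualifiers: frozenset[str]
    term_id: str
    evidence_code: str
    aspect: str
    synonyms: frozenset[str] = field(default_factory=frozenset)

    @property
    def is_negated(self) -> bool:
        """True for NOT-qualified annotations (assertions of non-membership)."""
        return "NOT" in self.qualifiers


def _split_pipe(value: str) -> frozenset[str]:
    return frozenset(part for part in value.split("|") if part)


def parse_gaf(stream: IO[str]) -> list[AnnotationRecord]:
    """Parse a GAF document into a list of :class:`AnnotationRecord`.

    Lines starting with ``!`` are comments; a comments-only file yields
    an empty list. A data line with fewer than 15 tab-separated columns
    raises :class:`GafParseError` naming the line number.
    """
    records: list[AnnotationRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < _MIN_COLUMNS:
            raise GafParseError(
                f"expected >= {_MIN_COLUMNS} tab-separated columns, got {len(cols)}",
                line=lineno,
            )
        gene_id = cols[_COL_GENE].strip()
        term_id = cols[_COL_TERM].strip()
        evidence = cols[_COL_EVIDENCE].strip()
        if not gene_id or not term_id:
            raise GafParseError("empty gene or term identifier", line=lineno)
        if not evidence:
            raise GafParseError("empty evidence code", line=lineno)
        records.append(
            AnnotationRecord(
                db=cols[_COL_DB].strip(),
                gene_id=gene_id,
                symbol=cols[_COL_SYMBOL].strip(),
                qualifiers=_split_pipe(cols[_COL_QUALIFIER].strip()),
                term_id=term_id,
                evidence_code=evidence,
                aspect=cols[_COL_ASPECT].strip(),
                synonyms=_split_pipe(cols[_COL_SYNONYM].strip()),
            )
        )
    return records


def filter_by_evidence(
    records: Iterable[AnnotationRecord],
    include: Optional[set[str]] = None,
    exclude: Optional[set[str]] = None,
) -> list[AnnotationRecord]:
    """Keep records whose evidence code passes the include/exclude filter.

    At most one of ``include`` / ``exclude`` may be non-empty; both empty
    (or None) keeps everything. Input order is preserved.
    """
    include = set(include or ())
    exclude = set(exclude or ())
    if include and exclude:
        raise ConfigurationError(
            "evidence include and exclude filters are mutually exclusive"
        )
    if include:
        return [r for r in records if r.evidence_code in include]
    if exclude:
        return [r for r in records if r.evidence_code not in exclude]
    return list(records)


def write_gaf(records: Iterable[AnnotationRecord], stream: IO[str]) -> None:
    """Write records as GAF 2.2 (17 columns); supports fixture round-trips."""
    stream.write("!gaf-version: 2.2\n")
    for rec in records:
        cols = [""] * 17
        cols[_COL_DB] = rec.db
        cols[_COL_GENE] = rec.gene_id
        cols[_COL_SYMBOL] = rec.symbol
        cols[_COL_QUALIFIER] = "|".join(sorted(rec.qualifiers))
        cols[_COL_TERM] = rec.term_id
        cols[5] = "REF:0000001"
        cols[_COL_EVIDENCE] = rec.evidence_code
        cols[_COL_ASPECT] = rec.aspect
        cols[9] = rec.symbol
        cols[_COL_SYNONYM] = "|".join(sorted(rec.synonyms))
        cols[11] = "gene"
        cols[12] = "taxon:10090"
        cols[13] = "20150101"
        cols[14] = "TEST"
        stream.write("\t".join(cols) + "\n")
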