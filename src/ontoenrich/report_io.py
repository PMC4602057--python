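"""Serialization of result tables: TSV, XLSX and a cross-linked HTML report.

The TSV and the spreadsheet carry identical content: one row per term,
with the counts (k, n, K, N), p, q and the hit genes for every query
set. The HTML report embeds the graph as a navigable node list whose
entries link to table rows and back, plus the DOT source for external
rendering; term and gene hyperlinks are built from configurable URL
templates (AmiGO-style term URLs and MGI-style gene URLs by default).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from html import escape
from pathlib import Path
from typing import IO, Mapping, Optional

from openpyxl import Workbook

from .analysis import ResultTable, TermResult
from .errors import ConfigurationError, ReportError
from .graph_view import DisplayGraph, render_dot

DEFAULT_TERM_URL = "http://amigo.geneontology.org/amigo/term/{id}"
DEFAULT_GENE_URL = "http://www.informatics.jax.org/marker/{id}"

_FORMATS = ("tsv", "xlsx", "html", "dot")


@dataclass
class ReportConfig:
    outdir: Path
    formats: tuple[str, ...] = ("tsv", "dot", "html")
    term_url: str = DEFAULT_TERM_URL
    gene_url: str = DEFAULT_GENE_URL
    basename: str = "results"
    symbols: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        bad = [f for f in self.formats if f not in _FORMATS]
        if bad or not self.formats:
            raise ConfigurationError(
                f"formats must be a non-empty subset of {_FORMATS}, got {self.formats}"
            )


def _fmt(x: float) -> str:
    return f"{x:.5e}"  # 6 significant digits, scientific


def _gene_cell(stats_genes, symbols: Mapping[str, str]) -> str:
    return ";".join(sorted(symbols.get(g, g) for g in stats_genes))


def _header(table: ResultTable) -> list[str]:
    cols = ["term_id", "term_name", "namespace"]
    for label in table.set_labels:
        cols += [f"{label}:{c}" for c in ("k", "n", "K", "N", "p", "q", "genes")]
    return cols


def _row_values(row: TermResult, table: ResultTable, symbols: Mapping[str, str]):
    values: list = [row.term_id, row.term_name, row.namespace]
    for label in table.set_labels:
        st = row.per_set[label]
        values += [st.k, st.n, st.K, st.N, st.p, st.q, _gene_cell(st.genes, symbols)]
    return values


def write_tsv(
    table: ResultTable, stream: IO[str], symbols: Optional[Mapping[str, str]] = None
) -> None:
    """Write the table as UTF-8 TSV; p and q in 6-digit scientific notation."""
    symbols = symbols or {}
    stream.write("\t".join(_header(table)) + "\n")
    for row in table.rows:
        out = []
        for v in _row_values(row, table, symbols):
            out.append(_fmt(v) if isinstance(v, float) else str(v))
        stream.write("\t".join(out) + "\n")


def write_xlsx(
    table: ResultTable, path: Path, symbols: Optional[Mapping[str, str]] = None
) -> None:
    """Write the table to one worksheet; count and probability cells numeric."""
    symbols = symbols or {}
    wb = Workbook()
    ws = wb.active
    ws.title = table.mode
    ws.append(_header(table))
    for row in table.rows:
        ws.append(_row_values(row, table, symbols))
    wb.save(path)


def _anchor(term_id: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", term_id)


def write_html(
    table: ResultTable,
    graph: DisplayGraph,
    stream: IO[str],
    term_url: str = DEFAULT_TERM_URL,
    gene_url: str = DEFAULT_GENE_URL,
    symbols: Optional[Mapping[str, str]] = None,
) -> None:
    """Emit a standalone HTML report with bidirectional row/node links.

    Every displayed non-root node must have a table row; the graph pane
    lists nodes linking to ``#row-<id>`` anchors and each row links back
    to ``#node-<id>``. Term/gene URLs come from the ``{id}`` templates.
    """
    symbols = symbols or {}
    tabled = {row.term_id for row in table.rows}
    missing = sorted(
        t for t, node in graph.nodes.items() if not node.is_root and t not in tabled
    )
    if missing:
        raise ReportError(
            f"displayed node(s) missing from table: {', '.join(missing)}"
        )

    w = stream.write
    w("<!DOCTYPE html>\n<html><head><meta charset='utf-8'>\n")
    w(f"<title>Term {escape(table.mode)} report</title>\n")
    w(
        "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:2px 6px;font:12px sans-serif}.node{display:inline-block;"
        "border:1px solid #333;border-radius:4px;margin:3px;padding:4px}</style>\n"
    )
    w("</head><body>\n")
    w(f"<h1>Term {escape(table.mode)} results</h1>\n")

    w("<h2 id='graph'>Graph</h2>\n<div>\n")
    for term_id in sorted(graph.nodes):
        node = graph.nodes[term_id]
        a = _anchor(term_id)
        label = " / ".join(escape(s) for s in node.label_lines if s)
        if term_id in tabled:
            w(
                f"<span class='node' id='node-{a}'>"
                f"<a href='#row-{a}'>{label}</a></span>\n"
            )
        else:
            w(f"<span class='node' id='node-{a}'>{label}</span>\n")
    w("</div>\n")
    w("<details><summary>DOT source</summary><pre>\n")
    w(escape(render_dot(graph)))
    w("</pre></details>\n")

    w("<h2 id='table'>Table</h2>\n<table>\n<tr><th></th>")
    for col in _header(table):
        w(f"<th>{escape(col)}</th>")
    w("</tr>\n")
    for row in table.rows:
        a = _anchor(row.term_id)
        w(f"<tr id='row-{a}'>")
        if row.term_id in graph.nodes:
            w(f"<td><a href='#node-{a}'>&#9679;</a></td>")
        else:
            w("<td></td>")
        href = term_url.replace("{id}", row.term_id)
        w(
            f"<td><a href='{escape(href, quote=True)}'>{escape(row.term_id)}</a></td>"
            f"<td>{escape(row.term_name)}</td><td>{escape(row.namespace)}</td>"
        )
        for label in table.set_labels:
            st = row.per_set[label]
            genes = ", ".join(
                f"<a href='{escape(gene_url.replace('{id}', g), quote=True)}'>"
                f"{escape(symbols.get(g, g))}</a>"
                for g in sorted(st.genes)
            )
            w(
                f"<td>{st.k}</td><td>{st.n}</td><td>{st.K}</td><td>{st.N}</td>"
                f"<td>{_fmt(st.p)}</td><td>{_fmt(st.q)}</td><td>{genes}</td>"
            )
        w("</tr>\n")
    w("</table>\n</body></html>\n")


def write_reports(
    config: ReportConfig, table: ResultTable, graph: DisplayGraph
) -> dict[str, Path]:
    """Write every requested format into ``config.outdir``; returns paths."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    base = config.outdir / config.basename
    if "tsv" in config.formats:
        paths["tsv"] = base.with_suffix(".tsv")
        with open(paths["tsv"], "w", encoding="utf-8", newline="") as fh:
            write_tsv(table, fh, symbols=config.symbols)
    if "xlsx" in config.formats:
        paths["xlsx"] = base.with_suffix(".xlsx")
        write_xlsx(table, paths["xlsx"], symbols=config.symbols)
    if "dot" in config.formats:
        paths["dot"] = base.with_suffix(".dot")
        paths["dot"].write_text(render_dot(graph), encoding="utf-8")
    if "html" in config.formats:
        paths["html"] = base.with_suffix(".html")
        with open(paths["html"], "w", encoding="utf-8") as fh:
            write_html(
                table,
                graph,
                fh,
                term_url=config.term_url,
                gene_url=config.gene_url,
                symbols=config.symbols,
            )
    return paths
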