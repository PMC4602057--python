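"""Pruned, styled DAG views of enrichment results, serialized to DOT.

The display graph shows the most significant terms in their ontology
context. With culling on (the default) only the selected terms and the
namespace roots are drawn, and every maximal run of hidden ancestors
between two displayed terms collapses into a single generic edge;
direct parent-child pairs keep their typed relation. Node sizes grow
linearly with capped -log10(p) of the term's best (minimum) p-value,
and per-set bars show each set's own capped -log10(p).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from html import escape
from math import log10
from typing import Iterable, Optional

import networkx as nx

from .analysis import ResultTable
from .errors import GraphViewError
from .obo_io import Ontology, Relation

#: Pseudo-relation marking a collapsed multi-step path.
COLLAPSED = "collapsed"

_PALETTE = (
    "#e6c229",  # yellow
    "#4f81bd",  # blue
    "#9bbb59",
    "#c0504d",
    "#8064a2",
    "#4bacc6",
)


@dataclass(frozen=True)
class StyleConfig:
    """Colors, node-size scale and canvas options for the display graph."""

    cap: float = 10.0  # -log10(p) ceiling for size/bar scaling
    size_min: float = 0.4  # layout units (inches in DOT)
    size_max: float = 2.5
    is_a_color: str = "#2b5fad"  # blue, hollow arrow
    part_of_color: str = "#7d3c98"  # purple, diamond tip
    collapsed_color: str = "#000000"  # black, solid arrow
    positively_regulates_color: str = "#1e8449"
    negatively_regulates_color: str = "#c0392b"
    regulates_color: str = "#b7950b"
    node_fill: str = "#fffbe8"
    background: str = "#ffffff"
    set_colors: tuple[str, ...] = ()

    def color_for_set(self, i: int) -> str:
        if i < len(self.set_colors):
            return self.set_colors[i]
        return _PALETTE[i % len(_PALETTE)]


@dataclass
class DisplayNode:
    term_id: str
    label_lines: tuple[str, str, str]  # (id, name, formatted min-p)
    size: float
    bars: tuple[float, ...]  # per-set heights in [0, 1]
    is_root: bool = False


@dataclass(frozen=True)
class DisplayEdge:
    child_id: str
    parent_id: str
    relation: str  # a Relation value or COLLAPSED


@dataclass
class DisplayGraph:
    nodes: dict[str, DisplayNode]
    edges: frozenset[DisplayEdge]
    set_labels: tuple[str, ...]
    style: StyleConfig = field(default_factory=StyleConfig)


def select_nodes(
    table: ResultTable,
    max_nodes: int = 40,
    p_cutoff: Optional[float] = None,
    roots: Iterable[str] = (),
) -> set[str]:
    """Pick the ``max_nodes`` most significant terms, always plus the roots.

    ``p_cutoff`` (applied to the overall min-p score) may empty the
    selection; the roots are included regardless, so the view always has
    its anchor.
    """
    if max_nodes < 1:
        raise GraphViewError("max_nodes must be >= 1")
    rows = table.rows
    if p_cutoff is not None:
        rows = [r for r in rows if r.overall_score <= p_cutoff]
    selected = {r.term_id for r in rows[:max_nodes]}
    return selected | set(roots)


def _neglog10(p: float, cap: float) -> float:
    if p <= 0.0:
        return cap
    return min(-log10(p), cap)


def build_display_graph(
    ontology: Ontology,
    selected: set[str],
    table: ResultTable,
    cull: bool = True,
    style: Optional[StyleConfig] = None,
) -> DisplayGraph:
    """Assemble the displayed sub-DAG for a node selection.

    With ``cull=False`` every ancestor on a path from a selected term to
    its root is displayed with its own score; with ``cull=True`` only
    the selection and the roots appear and hidden stretches become
    single COLLAPSED edges. Reachability between displayed terms always
    matches ancestry in the full ontology.
    """
    style = style or StyleConfig()
    if not style.set_colors and table.set_colors:
        style = replace(style, set_colors=table.set_colors)
    unknown = sorted(t for t in selected if t not in ontology.terms)
    if unknown:
        raise GraphViewError(f"selected term(s) not in ontology: {', '.join(unknown)}")

    full = ontology.graph()  # child -> parent, all relations
    namespaces = {ontology.terms[t].namespace for t in selected}
    roots = {
        ontology.roots[ns] for ns in namespaces if ns in ontology.roots
    }
    roots |= {t for t in selected if t in set(ontology.roots.values())}

    if cull:
        displayed = set(selected) | roots
    else:
        displayed = set(selected) | roots
        for term in selected:
            displayed |= nx.descendants(full, term)  # ancestors of term

    typed_edges: set[DisplayEdge] = set()
    for child, parent, rel in ontology.edges:
        if child in displayed and parent in displayed:
            typed_edges.add(DisplayEdge(child, parent, rel.value))

    edges = set(typed_edges)
    if cull:
        direct_pairs = {(e.child_id, e.parent_id) for e in typed_edges}
        for term in sorted(displayed):
            for ancestor in _closest_displayed_ancestors(full, term, displayed):
                if (term, ancestor) not in direct_pairs:
                    edges.add(DisplayEdge(term, ancestor, COLLAPSED))

    by_term = {row.term_id: row for row in table.rows}
    nodes: dict[str, DisplayNode] = {}
    for term_id in sorted(displayed):
        row = by_term.get(term_id)
        if row is not None:
            p_min = row.overall_score
            bars = tuple(
                _neglog10(row.per_set[label].p, style.cap) / style.cap
                for label in table.set_labels
            )
        else:
            p_min = 1.0
            bars = tuple(0.0 for _ in table.set_labels)
        frac = _neglog10(p_min, style.cap) / style.cap
        nodes[term_id] = DisplayNode(
            term_id=term_id,
            label_lines=(term_id, ontology.terms[term_id].name, f"{p_min:.2e}"),
            size=style.size_min + (style.size_max - style.size_min) * frac,
            bars=bars,
            is_root=term_id in roots,
        )
    return DisplayGraph(
        nodes=nodes,
        edges=frozenset(edges),
        set_labels=table.set_labels,
        style=style,
    )


def _closest_displayed_ancestors(
    full: nx.DiGraph, term: str, displayed: set[str]
) -> set[str]:
    """Displayed ancestors reachable from ``term`` through hidden nodes only,
    with at least one hidden hop on the way."""
    found: set[str] = set()
    seen: set[str] = set()
    # start from hidden parents only: displayed parents are direct edges
    stack = [p for p in full.successors(term) if p not in displayed]
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        for parent in full.successors(node):
            if parent in displayed:
                found.add(parent)
            elif parent not in seen:
                stack.append(parent)
    return found


_EDGE_STYLE = {
    Relation.IS_A.value: ("is_a_color", "empty", "solid"),
    Relation.PART_OF.value: ("part_of_color", "diamond", "solid"),
    Relation.POSITIVELY_REGULATES.value: ("positively_regulates_color", "vee", "solid"),
    Relation.NEGATIVELY_REGULATES.value: ("negatively_regulates_color", "tee", "solid"),
    Relation.REGULATES.value: ("regulates_color", "odot", "solid"),
    COLLAPSED: ("collapsed_color", "normal", "solid"),
}


def _node_label(node: DisplayNode, style: StyleConfig) -> str:
    tid, name, score = (escape(s) for s in node.label_lines)
    rows = [
        f'<tr><td align="center"><b>{tid}</b></td></tr>',
        f'<tr><td align="center">{name}</td></tr>',
        f'<tr><td align="center">{score}</td></tr>',
    ]
    if node.bars:
        cells = "".join(
            f'<td bgcolor="{style.color_for_set(i)}" width="16" '
            f'height="{int(round(4 + 16 * h))}"></td>'
            for i, h in enumerate(node.bars)
        )
        rows.append(
            '<tr><td align="center"><table border="0" cellborder="0" '
            f'cellspacing="2"><tr>{cells}</tr></table></td></tr>'
        )
    return (
        '<<table border="0" cellborder="0" cellspacing="0">'
        + "".join(rows)
        + "</table>>"
    )


def render_dot(graph: DisplayGraph) -> str:
    """Emit deterministic Graphviz DOT text for a :class:`DisplayGraph`.

    Node and edge statements are sorted by term id, so repeated renders
    of the same graph are byte-identical.
    """
    style = graph.style
    lines = [
        "digraph enrichment {",
        f'  bgcolor="{style.background}";',
        "  rankdir=BT;",
        f'  node [shape=box, style="rounded,filled", fillcolor="{style.node_fill}"];',
    ]
    for term_id in sorted(graph.nodes):
        node = graph.nodes[term_id]
        size = f"{node.size:.3f}"
        attrs = [
            f"label={_node_label(node, style)}",
            f"width={size}",
            f"height={size}",
            f'tooltip="{escape(node.term_id)}"',
        ]
        if node.is_root:
            attrs.append("penwidth=2")
        lines.append(f'  "{term_id}" [{", ".join(attrs)}];')
    for edge in sorted(
        graph.edges, key=lambda e: (e.child_id, e.parent_id, e.relation)
    ):
        color_attr, arrowhead, line_style = _EDGE_STYLE[edge.relation]
        color = getattr(style, color_attr)
        lines.append(
            f'  "{edge.child_id}" -> "{edge.parent_id}" '
            f'[color="{color}", arrowhead={arrowhead}, style={line_style}, '
            f'edgetooltip="{edge.relation}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
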