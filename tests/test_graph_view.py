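import networkx as nx
import pytest

from ontoenrich.analysis import analyze
from ontoenrich.annotation_index import QuerySet, build_index, resolve_query
from ontoenrich.errors import GraphViewError
from ontoenrich.fixtures import FixtureSpec, PlantedSignal, generate
from ontoenrich.graph_view import (
    COLLAPSED,
    StyleConfig,
    build_display_graph,
    render_dot,
    select_nodes,
)
from ontoenrich.obo_io import Ontology, Relation, Term

from conftest import chain_ontology, make_record

R = "TST:0000000"
CHAIN = ["TST:0000000", "TST:0000010", "TST:0000011", "TST:0000012"]


@pytest.fixture
def planted_run():
    onto, records, query = generate(
        FixtureSpec(seed=2, n_terms=40, n_genes=200,
                    planted=PlantedSignal(4, 30, 22, closure_size=50))
    )
    idx = build_index(onto, records)
    table = analyze([resolve_query(query, idx)], idx)
    return onto, table


def test_select_all_when_budget_large(planted_run):
    onto, table = planted_run
    sel = select_nodes(table, max_nodes=10_000, roots=onto.roots.values())
    assert sel == {r.term_id for r in table.rows} | set(onto.roots.values())


def test_select_cutoff_below_everything_keeps_roots_only(planted_run):
    onto, table = planted_run
    sel = select_nodes(table, max_nodes=10, p_cutoff=0.0, roots=onto.roots.values())
    assert sel == set(onto.roots.values())


def test_select_top_two_plus_root(planted_run):
    onto, table = planted_run
    sel = select_nodes(table, max_nodes=2, roots=onto.roots.values())
    best = {r.term_id for r in table.rows[:2]}
    assert sel == best | set(onto.roots.values())


def chain_table(onto):
    records = [make_record(f"g{i}", CHAIN[-1]) for i in range(3)] + [
        make_record("g9", CHAIN[0])
    ]
    idx = build_index(onto, records)
    return idx, analyze([QuerySet("q", "#000", frozenset({"g0", "g1"}))], idx)


def test_chain_cull_collapses_hidden_path():
    onto = chain_ontology()
    _, table = chain_table(onto)
    graph = build_display_graph(onto, {CHAIN[-1], CHAIN[0]}, table, cull=True)
    assert set(graph.nodes) == {CHAIN[0], CHAIN[-1]}
    (edge,) = graph.edges
    assert (edge.child_id, edge.parent_id, edge.relation) == (
        CHAIN[-1], CHAIN[0], COLLAPSED
    )


def test_chain_no_cull_shows_full_path_with_typed_edges():
    onto = chain_ontology()
    _, table = chain_table(onto)
    graph = build_display_graph(onto, {CHAIN[-1], CHAIN[0]}, table, cull=False)
    assert set(graph.nodes) == set(CHAIN)
    assert all(e.relation == Relation.IS_A.value for e in graph.edges)
    assert len(graph.edges) == 3


def test_siblings_keep_typed_edges_no_collapse(small_index, three_term_ontology):
    table = analyze(
        [QuerySet("q", "#000", frozenset({"g1", "g2"}))], small_index,
        keep_zero_rows=True,
    )
    graph = build_display_graph(
        three_term_ontology,
        {"TST:0000001", "TST:0000002", R},
        table,
        cull=True,
    )
    rels = {e.relation for e in graph.edges}
    assert COLLAPSED not in rels
    assert rels == {Relation.IS_A.value, Relation.PART_OF.value}


def test_unknown_selected_term_is_an_error(planted_run):
    onto, table = planted_run
    with pytest.raises(GraphViewError, match="GHOST:1"):
        build_display_graph(onto, {"GHOST:1"}, table)


def test_root_always_present_even_for_empty_selection(planted_run):
    onto, table = planted_run
    root = onto.roots["biological_process"]
    graph = build_display_graph(onto, {root}, table, cull=True)
    assert set(graph.nodes) == {root}
    assert graph.nodes[root].is_root


def test_size_monotone_in_significance(planted_run):
    onto, table = planted_run
    sel = select_nodes(table, max_nodes=20, roots=onto.roots.values())
    graph = build_display_graph(onto, sel, table)
    scored = [
        (table.row_for(t).overall_score, graph.nodes[t].size)
        for t in graph.nodes
        if table.row_for(t) is not None
    ]
    scored.sort()
    sizes = [s for _, s in scored]
    assert all(a >= b - 1e-12 for a, b in zip(sizes, sizes[1:]))
    smin, smax = StyleConfig().size_min, StyleConfig().size_max
    assert all(smin - 1e-12 <= s <= smax + 1e-12 for s in sizes)


@pytest.mark.parametrize("seed", range(4))
def test_reachability_matches_transitive_closure_oracle(seed):
    """Displayed-graph reachability == ancestry in the full ontology."""
    onto, records, query = generate(
        FixtureSpec(seed=seed, n_terms=50, n_genes=80,
                    planted=PlantedSignal(3, 15, 10, closure_size=25))
    )
    idx = build_index(onto, records)
    table = analyze([resolve_query(query, idx)], idx)
    sel = select_nodes(table, max_nodes=8, roots=onto.roots.values())
    graph = build_display_graph(onto, sel, table, cull=True)
    assert set(graph.nodes) == sel  # culled node set == selection ∪ roots

    full = nx.DiGraph()
    full.add_nodes_from(onto.terms)
    full.add_edges_from((c, p) for c, p, _ in onto.edges)
    disp = nx.DiGraph()
    disp.add_nodes_from(graph.nodes)
    disp.add_edges_from((e.child_id, e.parent_id) for e in graph.edges)
    for u in graph.nodes:
        full_anc = nx.descendants(full, u)  # ancestors (edges child->parent)
        disp_anc = nx.descendants(disp, u)
        assert disp_anc == full_anc & set(graph.nodes), u
    # every COLLAPSED edge hides at least one node on every... some path
    for e in graph.edges:
        if e.relation == COLLAPSED:
            assert (e.child_id, e.parent_id) not in full.edges or any(
                node not in graph.nodes
                for path in nx.all_simple_paths(full, e.child_id, e.parent_id)
                for node in path[1:-1]
            )


def test_render_dot_single_root():
    onto = Ontology()
    onto.terms["X:0"] = Term(id="X:0", name="root", namespace="ns")
    onto.roots = {"ns": "X:0"}
    idx_records = [make_record("g1", "X:0")]
    idx = build_index(onto, idx_records)
    table = analyze([QuerySet("q", "#000", frozenset({"g1"}))], idx)
    graph = build_display_graph(onto, {"X:0"}, table)
    dot = render_dot(graph)
    assert dot.count('"X:0" [') == 1
    assert "->" not in dot


def test_render_dot_collapsed_style_and_determinism():
    onto = chain_ontology()
    _, table = chain_table(onto)
    graph = build_display_graph(onto, {CHAIN[-1], CHAIN[0]}, table, cull=True)
    dot = render_dot(graph)
    assert dot == render_dot(graph)  # byte-identical
    style = StyleConfig()
    assert dot.count(" [label=") == 2  # node statements
    assert dot.count("->") == 1
    assert f'color="{style.collapsed_color}", arrowhead=normal' in dot


def test_render_dot_relation_styles(three_term_ontology, small_index):
    table = analyze(
        [QuerySet("q", "#000", frozenset({"g1", "g2", "g3"}))], small_index
    )
    sel = {"TST:0000001", "TST:0000002", R}
    graph = build_display_graph(three_term_ontology, sel, table)
    dot = render_dot(graph)
    style = StyleConfig()
    assert f'color="{style.is_a_color}", arrowhead=empty' in dot
    assert f'color="{style.part_of_color}", arrowhead=diamond' in dot
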