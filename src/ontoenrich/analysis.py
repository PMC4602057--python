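"""Per-term statistics for one or more query sets, assembled into a table.

Each query set is analyzed independently against the same annotation
index; results are juxtaposed per term so that differences between the
sets (e.g. up- vs down-regulated genes) are visible side by side. A
term's overall score is the minimum p-value across the sets, and the
table is sorted by that score ascending (most significant first).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .annotation_index import AnnotationIndex, QuerySet
from .errors import ConfigurationError, QueryError
from .stats import depletion_pvalue, enrichment_pvalue, estimate_pi0, qvalues

MODE_ENRICHMENT = "enrichment"
MODE_DEPLETION = "depletion"


@dataclass
class TermStats:
    """Hypergeometric counts and significance for one (term, query set)."""

    k: int
    n: int
    K: int
    N: int
    p: float
    q: float = 1.0
    genes: tuple[str, ...] = ()


@dataclass
class TermResult:
    term_id: str
    term_name: str
    namespace: str
    per_set: dict[str, TermStats]

    @property
    def overall_score(self) -> float:
        return min(st.p for st in self.per_set.values())

    @property
    def max_K(self) -> int:
        return max(st.K for st in self.per_set.values())


@dataclass
class ResultTable:
    rows: list[TermResult]
    mode: str
    set_labels: tuple[str, ...]
    set_colors: tuple[str, ...]
    parameters: dict = field(default_factory=dict)

    def row_for(self, term_id: str) -> TermResult | None:
        for row in self.rows:
            if row.term_id == term_id:
                return row
        return None


def analyze(
    query_sets: Sequence[QuerySet],
    index: AnnotationIndex,
    mode: str = MODE_ENRICHMENT,
    keep_zero_rows: bool = False,
    pooled_universe: bool = False,
    pi0_estimate: bool = False,
) -> ResultTable:
    """Compute per-term enrichment or depletion statistics for every set.

    For each term t with a non-empty closure and each query set s:
    k = |genes_s ∩ closure(t)|, n = |genes_s ∩ namespace universe|,
    K = |closure(t)|, N per the universe policy; p is the upper
    (enrichment) or lower (depletion) hypergeometric tail. q-values are
    computed within each (set, namespace) over its m = number of K >= 1
    terms. Rows with k = 0 in every set are dropped in enrichment mode
    unless ``keep_zero_rows`` (depletion keeps them: absence is the
    signal).
    """
    if not query_sets:
        raise QueryError("at least one query set is required")
    for qs in query_sets:
        if not qs.genes:
            raise QueryError(f"query set {qs.label!r} is empty")
    if mode not in (MODE_ENRICHMENT, MODE_DEPLETION):
        raise ConfigurationError(f"unknown mode {mode!r}")
    labels = [qs.label for qs in query_sets]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("query set labels must be unique")

    pvalue = enrichment_pvalue if mode == MODE_ENRICHMENT else depletion_pvalue

    terms_by_ns: dict[str, list[str]] = {}
    for term_id in index.closed_genes:
        terms_by_ns.setdefault(index.term_namespaces[term_id], []).append(term_id)

    stats: dict[str, dict[str, TermStats]] = {t: {} for t in index.closed_genes}
    for qs in query_sets:
        for ns, term_ids in sorted(terms_by_ns.items()):
            universe = index.universe if pooled_universe else index.namespace_universe[ns]
            N = len(universe)
            genes_ns = qs.genes & universe
            n = len(genes_ns)
            ps = []
            for term_id in sorted(term_ids):
                closure = index.closed_genes[term_id]
                hits = genes_ns & closure
                K = len(closure)
                p = pvalue(len(hits), n, K, N)
                stats[term_id][qs.label] = TermStats(
                    k=len(hits), n=n, K=K, N=N, p=p, genes=tuple(sorted(hits))
                )
                ps.append(p)
            pi0 = estimate_pi0(ps) if pi0_estimate else 1.0
            qs_vals = qvalues(ps, m=len(ps), pi0=pi0)
            for term_id, q in zip(sorted(term_ids), qs_vals):
                stats[term_id][qs.label].q = float(q)

    rows = []
    for term_id, per_set in stats.items():
        if mode == MODE_ENRICHMENT and not keep_zero_rows:
            if all(st.k == 0 for st in per_set.values()):
                continue
        rows.append(
            TermResult(
                term_id=term_id,
                term_name=index.term_names.get(term_id, ""),
                namespace=index.term_namespaces.get(term_id, "default"),
                per_set=per_set,
            )
        )
    rows.sort(key=lambda r: (r.overall_score, -r.max_K, r.term_id))
    return ResultTable(
        rows=rows,
        mode=mode,
        set_labels=tuple(labels),
        set_colors=tuple(qs.color for qs in query_sets),
        parameters={
            "pooled_universe": pooled_universe,
            "keep_zero_rows": keep_zero_rows,
            "pi0_estimate": pi0_estimate,
        },
    )


def summarize_inputs(
    query_sets: Sequence[QuerySet], index: AnnotationIndex
) -> dict:
    """Run-provenance counts for report headers and logs."""
    return {
        "n_sets": len(query_sets),
        "sets": [
            {
                "label": qs.label,
                "resolved": len(qs.genes),
                "unresolved": len(qs.unresolved),
                "unresolved_tokens": list(qs.unresolved),
            }
            for qs in query_sets
        ],
        "N_per_namespace": {
            ns: len(genes) for ns, genes in sorted(index.namespace_universe.items())
        },
        "m_per_namespace": {
            ns: sum(
                1 for t, tns in index.term_namespaces.items() if tns == ns
            )
            for ns in sorted(index.namespace_universe)
        },
        "N_pooled": len(index.universe),
    }
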