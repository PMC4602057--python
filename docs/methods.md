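# Methods

## Model

Term over-representation is assessed with the hypergeometric (Fisher
one-tail) model. For a term *t*: N is the number of annotated genes in
the background, K the number annotated to *t* or any of its
descendants, n the number of query genes in the background and k the
query genes among the K. Enrichment tests P(X ≥ k), depletion
P(X ≤ k), with X ~ Hypergeometric(N, K, n). The model assumes the
query is an unordered sample without replacement from the background
and that annotations are fixed; it does not model annotation bias,
gene length, or inter-gene correlation.

### Annotation closure

The true-path rule is applied before counting: direct annotations
propagate to all ancestors reachable through `is_a` and `part_of`
edges (configurable; `regulates` edges are drawn in graphs but not
propagated by default, since regulation does not imply membership in
the regulated process). Closure is computed by one pass over the terms
in topological order, pushing each term's gene set to its parents —
O(|edges| · genes) with set union, exact, and independent of record
order. Records with a NOT qualifier are excluded (they assert
non-membership), as are records to unresolvable or obsolete terms;
alt_ids resolve to their primary term. Duplicate (gene, term) pairs
collapse to one.

### Universe policy

The default background is per namespace: each ontology namespace
(aspect) is a separate DAG, so N for a term is the number of genes
with at least one annotation in that term's namespace, and the root's
closure equals that universe by construction. Pooling the three GO
aspects into one N would deflate p-values in well-annotated aspects;
`--pooled-universe` restores the single-N behaviour for comparison.
A user-supplied universe is intersected with the annotated genes
(the test is defined over annotated genes); with `--pooled-universe
--count-unannotated` the full custom list is counted in N instead.
Query tokens are matched case-insensitively against gene ids, then
symbols, then synonyms — exact match only, ambiguous symbols resolving
to the smallest gene id so results cannot depend on file order. Tokens
that do not resolve, or resolve outside the universe, are reported
with a reason code rather than silently shrinking n.

### Multiple testing

q-values use the step-up estimator over the ordered p-values,
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ π₀ m p₍ⱼ₎ / j, clipped at 1, with π₀ = 1 by default —
conservative and exactly reproducible (identical to the
Benjamini–Hochberg adjusted p-value). An optional π₀ estimate uses the
λ = 0.5 census, #{p > λ} / (m(1 − λ)), floored at 1/m. m counts the
terms with K ≥ 1 in the analyzed namespace, per query set: terms with
no annotated genes cannot be significant, and counting them would
inflate m arbitrarily. q-values are therefore computed within each
(query set, namespace) block; the per-row q shown next to a set's
statistics is that set's own. The minimum-p overall score used for
sorting and node sizing is a ranking device, not a p-value, and never
enters the q computation. Sorting is deterministic: ascending overall
score, ties broken by larger closure then term id.

## Numerical choices

- Tail probabilities sum log-pmf terms (via log-gamma) from whichever
  tail has fewer support points, combined with logsumexp; the long
  tail is obtained as 1 − (short tail). This keeps small p-values at
  full relative precision (no 1 − cdf cancellation) and costs at most
  half the support per call. k at or below the lower support bound
  returns exactly 1.0 for enrichment; k = min(n, K) exactly 1.0 for
  depletion.
- p/q are serialized with 6 significant digits in scientific notation;
  TSV and XLSX carry identical values, with numeric cell types in the
  spreadsheet.
- Degenerate inputs: an empty record set after filtering, an empty
  query after resolution, or simultaneous include+exclude evidence
  filters are errors, reported before any output is written.

## Display graph

`select_nodes` keeps the `max_nodes` most significant table rows
(after an optional p cutoff) plus, always, the namespace roots — the
root anchors the reader even when nothing is significant. With culling
on (default) only selected terms and roots are drawn; each maximal run
of hidden ancestors between two displayed terms becomes one generic
"collapsed" edge, computed by an upward search from each displayed
node through hidden nodes to its closest displayed ancestors. This
preserves reachability exactly: a displayed term can reach another in
the view iff it is its ancestor in the full ontology. A direct
parent-child pair keeps its typed edge and suppresses any parallel
collapsed edge. With culling off, all interior ancestors appear with
their own scores and only typed edges are drawn.

Node size is linear in capped −log₁₀(p) of the term's minimum p:
size = s_min + (s_max − s_min)·min(−log₁₀ p, cap)/cap, with cap = 10
and sizes 0.4–2.5 layout units — the cap keeps astronomically small
p-values from exploding the canvas. Per-set bars use the same capped
scale absolutely (not renormalized per node), so bar heights are
comparable across nodes and monotone in each set's own significance.
Edge styling follows ontology-browser convention: is-a blue with a
hollow arrow, part-of purple with a diamond tip, collapsed black with
a solid arrow, the three regulates variants with distinct arrowheads;
all colors configurable. DOT output is sorted by term id and therefore
byte-stable across runs. Rasterization is left to an external
Graphviz installation; the DOT text is the contract, and the HTML
report embeds a navigable node list (bidirectionally linked to table
rows) plus the DOT source so it stands alone without a layout engine.

## Synthetic fixtures

The fixture generator emulates the combinatorial shape of curated
annotation corpora: a rooted random DAG (each new term attaches to
1..max_parents earlier terms; relation mix defaulting to 60% is_a /
25% part_of / 15% regulates; the first parent always a propagating
relation so every term has a true-path route to its root, as in GO), a
Poisson number of direct annotations per gene (mean 3, floored at 1 so
every gene is annotated), and optional planting of a signal: a
designated term, optionally forced to be a leaf with an exact closure
size, and a query with a chosen overlap into that closure. Defaults
(30 terms, 100 genes, one namespace) suit unit tests; the validation
suite scales to 1000 genes / 120 terms for signal recovery and
500 genes / 100 terms × 1000 random queries for null calibration.
Everything derives from a single integer seed.

What the fixtures do not emulate: the long-tailed term-size
distribution of real GO, annotation co-occurrence structure, evidence
code biases, and multi-species identifier mess. Passing tests
demonstrate correctness of the computation (closure, tails, q-values,
pruning) under the stated model — not that the hypergeometric model's
independence assumptions hold for any particular real dataset.

## Limitations

- One ontology + one annotation set per run; no cross-species mapping.
- No topology-weighted or model-based enrichment variants; the test is
  the classical closed-annotation hypergeometric.
- The culling heuristic draws only selected terms and roots; an
  interior term just below the selection cutoff is hidden even if
  biologically informative (raise `--max-nodes` or use `--no-cull`).
- OBO support covers the tag subset listed in `ontoenrich.obo_io`;
  OWL, logical definitions and cross-ontology imports are out of scope.
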