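# Methods

This note documents the models, rules and numerical choices behind
`kgcurate`, and what its synthetic benchmarks do and do not demonstrate.

## The knowledge-graph model

A knowledge graph is a directed multigraph of grounded entities (a
`(namespace, identifier)` pair from a terminology such as HGNC, ChEBI, GO,
MeSH, DOID, HP or FPLX) connected by typed, evidence-bearing edges. Edge
identity is `(subject, relation, object, citation, hash(evidence))`: the
same relation asserted from different evidence accumulates parallel edges,
while re-adding an identical statement is a no-op. The causal flag is a
pure function of the relation — exactly
`increases, directlyIncreases, decreases, directlyDecreases, regulates`
are causal; membership, variant, association, correlation and ontological
edges never are.

The BEL Script reader/writer covers a deliberate BEL 2.0 subset:
`p() g() r() m() a() complex() bp() path() act() pmod() var()`, with
reactions parsed as opaque nodes (pre-processing removes them anyway).
Namespaces are opaque prefixes validated only against the document's own
`DEFINE NAMESPACE` declarations; there are no live terminology lookups, and
real remapping tables plug in as two-column TSV files applied after parsing
(`recuration.apply_label_mapping`). Parsing is total: bad lines become
structured error records with line/column, never silent drops. The writer
sorts namespaces and statements (by citation, statement text, evidence), so
serialization is deterministic and parse/write round trips are idempotent —
properties the test suite checks on random graphs.

## Gene-level canonicalization

Novelty comparisons and degree computations run at *gene level*: variants
are stripped and gene products (gene, RNA, microRNA, protein) collapse onto
their grounding's key. Where only a protein-level grounding exists, that
key simply serves as the gene-level key; protein families with family-level
groundings (e.g. FPLX) are treated as gene-level nodes in their own right.
Relations collapse to coarse classes (`up`, `down`, `regulates`, `binds`,
`membership`, `other`); `binds` is symmetric, so its triples store
endpoints in sorted order. A triple with an ungroundable endpoint is marked
non-comparable and never matches anything — such statements are kept and
flagged for the curator rather than silently dropped.

Deduplication against the existing graph happens at this gene-collapsed
granularity (an extracted "activation" is considered known if the graph
has any `up` edge between the same genes, regardless of which gene product
it mentions). This is the looser of the two defensible choices; full-entity
strictness is available by comparing `Edge.identity` instead.

## Pre-processing and information density

`preprocess` keeps only causal edges whose endpoints are gene-level and not
in the excluded classes (default: chemical abundances, reactions,
pathologies, biological processes — configurable, since a metabolism-focused
effort would keep chemicals), collapses endpoints, and merges rewired
duplicates with identical (triple, citation, evidence). Self-loops arising
from collapsing (autoregulation, autophosphorylation) are kept and
contribute 2 to the density of their gene: they are causal information.
Entities that lose all edges remain as isolated nodes — these are exactly
the zero-density, highest-priority genes.

`information_density(g) = deg_in(g) + deg_out(g)` counts parallel edges
(evidences) by default, on the view that the quantity being proxied — how
much causal information the graph holds about the gene — accrues per
evidence, not per unique neighbor. `count_evidences=False` switches to
unique-triple counting. Ranking is ascending with lexicographic
tie-breaking by gene key, making it total, deterministic and
permutation-invariant; earlier rounds' genes are passed through `exclude`
so iterative application keeps surfacing fresh low-density genes. The
density function itself is a pluggable argument for experimentation with
alternatives (betweenness etc.), which are otherwise out of scope.

## Corpus triage

The corpus format is TSV with JSON mention columns, one row per extracted
statement: type (activation, inhibition, phosphorylation, other
modification, complex formation, amount regulation), candidate groundings
per participant, belief ∈ [0, 1], evidence sentence, citation, reader
tags, negation and physical-contact flags. Belief scores are consumed, not
computed. Grounding picks the candidate whose namespace appears earliest in
the policy's priority list (default `HGNC, FPLX, UP, CHEBI, GO, MESH,
DOID, HP`).

Filters: the novelty filter removes a statement only when it asserts at
least one comparable triple and *every* comparable triple it asserts is
already in the (un-preprocessed) graph. The belief filter keeps
`belief >= threshold` — the default 0.80 removes strictly-below scores,
so a statement at exactly 0.80 survives; a missing belief is treated as 0
and logged, a deliberately conservative choice. Both filters are
idempotent and commute; belief-filter output size is monotone
non-increasing in the threshold.

## Assembly semantics

Directness defaults to *indirect* (`increases`, not `directlyIncreases`)
because the direct/physical-contact distinction is unreliable in machine
reading; it upgrades only when the statement carries an explicit contact
flag. `act()` wrappers are suppressed on biological-process and pathology
objects (invalid BEL), with a fix record emitted. Negated statements are
never assembled — negation is an error class for curators, not an output.
Complex formation over *n* members emits `n + n(n−1)` edges (membership
plus ordered pairwise association); multiple modifications on one
statement would produce a single modified node with one `hasVariant` edge
(minimal-node principle). Every emitted edge carries the source statement's
uuid, evidence and citation.

## Sheets, marking protocol and statistics

Sheets are TSV (canonical, diff-able under version control; XLSX as an
alternate writer/reader) with a fixed 11-column header. The only truthy
mark is a literal `x`, case-insensitive; any other non-empty cell is a
finding. Ingestion enforces the protocol: decisions require `Checked`
(rule 1); `Correct` and `Changed` are mutually exclusive (rule 2); error
types must come from the controlled vocabulary (extensible via config) and
sit on changed or uncorrectable rows (rule 3); curator-added rows — those
outside the generated `(uuid, statement)` set, when that set is provided —
must share a known uuid and carry `Changed` but never `Correct` (rules
5–6). Row classification is total and mutually exclusive: correct ≻
changed ≻ uncorrectable (checked, neither mark) ≻ unchecked.

`summarize` excludes unchecked rows from every denominator. Percentages are
reported to one decimal, throughput to two; full precision is kept
internally. The group comparison of curation effort between the top-k and
bottom-k genes by extraction accuracy uses Welch's unequal-variance t-test
by default — the safer choice when variances may differ — with a flag for
the pooled-variance variant.

## Re-curation confidence workflow

Confidence is stored verbatim as the annotation strings `None, Low,
Medium, High, Very High` (with the space) for document fidelity; the
ordinal order lives in `ConfidenceLevel`. The state machine: second-curator
grading assigns `None` (delete), `Low`, `Medium` (after a fix) or `High`;
third-curator review is only legal from `Medium`/`High` and promotes to
`Very High` on agreement, otherwise records a fix with confidence
unchanged. `Very High` is reachable through no other path — verified by
randomized state-machine exploration. Deleting a nonsense evidence removes
every statement sharing that evidence string within the citation
(`scope="citation"` widens to the whole citation).

## Synthetic generators

`synth` emulates the study conditions end to end. The graph generator mixes
gene products (with occasional phosphorylated variants) and non-gene nodes
(processes, chemicals, pathologies; fraction 0.2) and draws 20% non-causal
relations. The corpus generator plants a truth label per statement from the
categorical distribution **0.31 correct / 0.48 fixable (split across six
error types, NER errors most common) / 0.21 uncorrectable**, matching the
outcome proportions a large curation exercise over text-mined statements
realistically produces; beliefs are drawn from Beta(5, 2) for correct and
Beta(2, 5) for corrupted rows so the 0.80 threshold has a visible precision
effect. A label-independent 5% of rows duplicate existing graph relations
so the novelty filter has real work without biasing the planted
proportions. The simulated curator is perfect: it marks exactly what the
planted label dictates. All generators are pure functions of
(config, seed).

What passing the closed loop shows: the bookkeeping chain (triage →
assembly → sheets → ingest → summarize) neither loses nor mislabels rows,
and recovers planted proportions within binomial sampling error. What it
does not show: robustness to real reader noise — evidence sentences are
templated, groundings are unambiguous, error types are independent of
sentence content, and the curator never disagrees with the truth. Real
corpora have correlated errors, ambiguous groundings and imperfect
inter-curator agreement.

In the closed-loop benchmark the belief filter is run fully open
(threshold 0): beliefs are label-dependent by construction, so filtering
at 0.80 would enrich for correct rows and distort the very proportions the
loop measures. Benchmark sizes — 60 genes, 200 edges, 5000 corpus
statements (≈11 000 sheet rows after assembly) — were chosen as the
smallest scale at which the 3σ binomial bands are comfortably inside a
2-percentage-point tolerance.

## Known limitations

- The BEL dialect omits lists, translocations, fusions and nested
  statements; reactions are opaque.
- Multi-curator conflict handling is last-writer-wins with a warning; no
  merge UI.
- The error-type vocabulary covers the categories that dominate in
  practice and is config-extensible, not exhaustive.
- Gene matching assumes the corpus and graph share gene-level namespaces;
  cross-namespace orthology mapping is out of scope.
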