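# kgcurate

Semi-automated curation tooling for knowledge graphs encoded in the
Biological Expression Language (BEL). Manually curated biomedical knowledge
graphs go stale: the literature grows faster than curators can read it, and
fully automated relation extraction is too noisy to trust unreviewed.
`kgcurate` implements the middle road — a *rational enrichment* loop that
spends curator time where the graph is thinnest, and a *re-curation* quality
gate for bringing legacy BEL documents up to standard. It is aimed at
biocuration teams maintaining BEL (or BEL-convertible) knowledge bases.

## What it does

**Rational enrichment.** Starting from a curated knowledge graph *G*:

1. **Pre-process** — collapse every gene product (RNA, microRNA, protein and
   modified variants) onto its gene, drop non-causal relations
   (association, correlation, ontological) and out-of-scope entity classes
   (chemical abundances, reactions, pathologies, biological processes),
   leaving the causal gene-level core.
2. **Rank by information density** — for gene *g*,
   `density(g) = deg_in(g) + deg_out(g)` in the pre-processed multigraph,
   counting one per evidence. Isolated genes (density 0) and leaves
   (density 1) are the genes the graph knows least about, so genes are
   ranked **ascending** and the top *k* (default 30) form one curation
   round.
3. **Triage a machine-extraction corpus** — query a dump of text-mined
   statements (each with candidate groundings, an evidence sentence, a
   citation and a belief score in [0, 1]) for the selected genes; drop
   statements whose gene-collapsed triple the graph already contains; drop
   statements with belief < 0.80 (precision over recall).
4. **Assemble candidate BEL** — activation/inhibition become
   `increases`/`decreases` onto the object's activity; phosphorylation adds
   a `pmod()` node plus a `hasVariant` edge from the reference protein;
   complex formation over *n* members yields a complex node, *n*
   `hasComponent` edges and *n(n−1)* pairwise bidirectional association
   statements. Directness is never asserted unless the reader flagged
   physical contact, and `act()` is never emitted on biological processes.
5. **Curation sheets** — one TSV per gene, one row per candidate statement,
   with `Checked` / `Correct` / `Changed` / `Error Type` / `Corrected BEL`
   decision columns filled by curators under a six-rule marking protocol,
   then validated and re-ingested.
6. **Score and merge** — recovered statements (correct as-is, or corrected)
   flow back into the graph; the report computes

   `recovery = (n_correct + n_changed) / n_evaluated`,

   per-gene accuracy, the error-type profile, and throughput in
   edges/minute.

**Re-curation.** A Likert confidence workflow for legacy documents: a second
curator grades each statement (`None` → delete with its evidence, `Low` →
discuss, `Medium` → fixed, `High` → assertable), and a third curator
promotes `Medium`/`High` statements to `Very High` on agreement — the only
path to `Very High`. `kgcurate qc check --required Confidence` exits
nonzero when any statement lacks the annotation, making it usable as a CI
gate.

Everything is testable offline: `kgcurate.synth` generates knowledge
graphs, corpora with planted error structure, and a perfect simulated
curator.

## Worked example

```bash
kgcurate fixtures --out fx --seed 3 --n-genes 25 --n-edges 80 --corpus-size 300
kgcurate round --kg fx/kg.bel --corpus fx/corpus.tsv --out round1 \
    --round-id r1 -k 5 --belief-threshold 0.5
```

The round manifest (`round1/r1_manifest.json`) records the five
lowest-density genes selected and the attrition at each filter stage:

```json
"attrition": {
  "corpus": 300,
  "queried": 119,
  "after_novelty_filter": 118,
  "after_belief_filter": 103,
  "assembled_statements": 103,
  "assembled_edges": 103
}
```

300 corpus statements → 119 mention a selected gene → 118 are novel (one
already in the graph) → 103 survive the belief cut and assemble into
candidate edges, written as per-gene sheets. After filling the sheets (here
with the simulated curator) and scoring:

```bash
kgcurate stats filled.tsv --hours 2
```

```
Evaluated statements : 103
  correct            : 85 (82.5%)
  changed            : 12 (11.7%)
  uncorrectable      : 6 (5.8%)
Recovery rate        : 94.2%
Throughput           : 0.81 edges/min
Error types:
  no_relation_in_evidence     : 7
  ner_wrong_entity            : 2
  ...
```

82.5% of the evaluated candidates were correct as extracted, 11.7% were
fixed by the curator, and 94.2% ended up usable — far above what a raw
extraction dump achieves, because the belief filter already removed most
corrupted statements (the synthetic generator draws lower belief scores for
corrupted rows, so tightening `--belief-threshold` trades recall for
precision). Finally, `kgcurate merge --kg fx/kg.bel filled.tsv -o
enriched.bel` writes the grown graph.

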