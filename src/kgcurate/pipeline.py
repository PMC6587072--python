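"""End-to-end orchestration of one enrichment round and of merging curated
rows back into the knowledge graph.

A round runs: preprocess → rank by information density → select the k
lowest-density genes → query the extraction corpus → drop already-known
relations → drop low-belief statements → assemble candidate BEL edges →
write per-gene curation sheets. The round manifest records the genes
selected and the attrition at every filter stage, so a round is reproducible
from (inputs, config, seed) alone.

Merging consumes ingested curation rows: rows marked correct contribute
their statement as-is, rows marked changed contribute their corrected
statement, uncorrectable and unchecked rows contribute nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .assembly import AssemblyPolicy, assemble
from .belscript import parse_statement_line
from .corpus import CorpusQueryConfig, ExtractedStatement, filter_belief, filter_novel, query_corpus
from .enrichment import DEFAULT_ROUND_SIZE, PreprocessConfig, preprocess, rank_genes, select_round
from .model import Edge, KnowledgeGraph
from .sheets import CurationRow, RowClass, classify_row, generate_sheets

__all__ = ["RoundResult", "MergeReport", "run_round", "merge_rows"]


@dataclass
class RoundResult:
    round_id: str
    genes: list[str]
    sheet_paths: list[Path]
    statements_per_gene: dict[str, int]
    attrition: dict[str, int]
    skips: list = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "round_id": self.round_id,
            "genes": self.genes,
            "sheets": [p.name for p in self.sheet_paths],
            "statements_per_gene": self.statements_per_gene,
            "attrition": self.attrition,
            "skipped": [s.to_json() for s in self.skips],
        }

    def write_manifest(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_round(
    kg: KnowledgeGraph,
    statements: list[ExtractedStatement],
    round_id: str,
    out_dir: Union[str, Path],
    k: int = DEFAULT_ROUND_SIZE,
    exclude: Iterable[str] = (),
    preprocess_config: PreprocessConfig = PreprocessConfig(),
    query_config: CorpusQueryConfig = CorpusQueryConfig(),
    policy: AssemblyPolicy = AssemblyPolicy(),
    combined_sheet: bool = False,
    sheet_format: str = "tsv",
) -> RoundResult:
    """Execute one enrichment round and write its curation sheets.

    Novelty is checked against the *original* (un-preprocessed) graph. A
    statement matching several selected genes is bundled under the first in
    sorted order, so no statement is curated twice.
    """
    pre = preprocess(kg, preprocess_config)
    ranked = rank_genes(pre, exclude=exclude)
    genes = select_round(ranked, k)

    queried = query_corpus(statements, genes, policy.namespace_priority)
    after_novel = (
        filter_novel(queried, kg, policy.namespace_priority) if query_config.exclude_existing else queried
    )
    after_belief = filter_belief(after_novel, query_config.belief_threshold)

    bundles: dict[str, list[Edge]] = {g: [] for g in genes}
    skips = []
    n_assembled_statements = 0
    for stmt in after_belief:
        result = assemble(stmt, policy)
        skips.extend(result.skips)
        if not result.edges:
            continue
        n_assembled_statements += 1
        gene = stmt.matched_genes[0] if stmt.matched_genes else genes[0]
        bundles.setdefault(gene, []).extend(result.edges)

    bundles = {g: edges for g, edges in bundles.items() if edges}
    sheet_paths = generate_sheets(bundles, round_id, out_dir, combined=combined_sheet, fmt=sheet_format)

    return RoundResult(
        round_id=round_id,
        genes=genes,
        sheet_paths=sheet_paths,
        statements_per_gene={g: len(edges) for g, edges in sorted(bundles.items())},
        attrition={
            "corpus": len(statements),
            "queried": len(queried),
            "after_novelty_filter": len(after_novel),
            "after_belief_filter": len(after_belief),
            "assembled_statements": n_assembled_statements,
            "assembled_edges": sum(len(e) for e in bundles.values()),
            "skipped_statements": len(skips),
        },
        skips=skips,
    )


@dataclass
class MergeReport:
    n_added: int = 0
    n_excluded: int = 0
    errors: list[dict] = field(default_factory=list)


def merge_rows(kg: KnowledgeGraph, rows: Iterable[CurationRow]) -> tuple[KnowledgeGraph, MergeReport]:
    """Append recovered (correct or corrected) statements to a copy of the
    graph. Unparseable corrected statements are reported per row and
    skipped; uncorrectable and unchecked rows are excluded."""
    out = kg.copy()
    report = MergeReport()
    for i, row in enumerate(rows):
        cls = classify_row(row)
        if cls in (RowClass.UNCORRECTABLE, RowClass.UNCHECKED):
            report.n_excluded += 1
            continue
        if cls is RowClass.CORRECT:
            text = row.bel_statement
        else:  # changed
            if not row.corrected_bel:
                report.errors.append({"row": i, "uuid": row.uuid, "error": "changed row lacks a corrected statement"})
                continue
            text = row.corrected_bel
        try:
            subject, relation, obj, s_act, o_act = parse_statement_line(text)
        except Exception as exc:  # structured row-level error, row skipped
            report.errors.append({"row": i, "uuid": row.uuid, "error": str(exc)})
            continue
        annotations = {"uuid": row.uuid}
        if row.curator:
            annotations["Curator"] = row.curator
        if s_act:
            annotations["_subject_activity"] = "true"
        if o_act:
            annotations["_object_activity"] = "true"
        out.add_edge(
            Edge(
                subject=subject,
                object=obj,
                relation=relation,
                evidence_text=row.evidence,
                citation=row.reference,
                annotations=annotations,
            )
        )
        report.n_added += 1
    return out, report
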