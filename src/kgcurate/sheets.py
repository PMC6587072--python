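"""Curation sheets: generation, validation and re-ingestion.

A curation sheet is a table of candidate BEL statements, one row per
assembled edge, with decision columns the curator fills in by hand:

* ``Checked`` — an ``x`` once the row has been looked at (rule 1);
* ``Correct`` — an ``x`` when the BEL statement correctly captures the
  evidence sentence (rule 2);
* ``Changed`` — an ``x`` when the statement had to be corrected; the error
  category goes in ``Error Type`` (controlled vocabulary) and the fixed
  statement in ``Corrected BEL`` (rule 3);
* neither mark, with Checked set — the statement does not correspond to the
  evidence and cannot be fixed (rule 4);
* curator-added rows for additional statements found in the same evidence
  duplicate the original row's provenance (uuid, reference, evidence) and
  carry Changed but never Correct (rules 5–6).

The canonical on-disk format is TSV with a fixed header — diff-able under
version control — with XLSX supported as an alternate writer/reader. The
only truthy mark is a literal ``x`` (case-insensitive); any other non-empty
cell is a validation finding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

from .model import Edge
from .belscript import statement_to_bel

__all__ = [
    "ErrorType",
    "CurationRow",
    "RowClass",
    "Finding",
    "IngestResult",
    "SHEET_COLUMNS",
    "rows_from_edges",
    "generate_sheets",
    "write_sheet",
    "ingest_sheet",
    "classify_row",
]


class ErrorType(str, Enum):
    """Controlled vocabulary of curation error categories.

    Named-entity recognition mistakes dominate in practice; the rest cover
    swapped subject/object, evidence sentences with no relation at all,
    missed negation words, wrong direct/indirect choice, dropped
    modifications, and malformed statement structure.
    """

    NER_WRONG_ENTITY = "ner_wrong_entity"
    SUBJECT_OBJECT_SWAP = "subject_object_swap"
    NO_RELATION_IN_EVIDENCE = "no_relation_in_evidence"
    NEGATION_MISSED = "negation_missed"
    DIRECT_INDIRECT = "direct_indirect"
    MISSING_MODIFICATION = "missing_modification"
    GRAMMAR_STRUCTURE = "grammar_structure"
    OTHER = "other"


SHEET_COLUMNS = [
    "uuid",
    "gene",
    "reference",
    "evidence",
    "bel",
    "checked",
    "correct",
    "changed",
    "error_type",
    "corrected_bel",
    "curator",
]


@dataclass(frozen=True)
class CurationRow:
    uuid: str
    gene_key: str
    reference: str
    evidence: str
    bel_statement: str
    checked: bool = False
    correct: bool = False
    changed: bool = False
    error_type: Optional[str] = None
    corrected_bel: Optional[str] = None
    curator: Optional[str] = None
    machine_origin: bool = True


class RowClass(str, Enum):
    CORRECT = "correct"
    CHANGED = "changed"
    UNCORRECTABLE = "uncorrectable"
    UNCHECKED = "unchecked"


@dataclass(frozen=True)
class Finding:
    row: int
    rule: str
    message: str

    def to_json(self) -> str:
        return json.dumps({"row": self.row, "rule": self.rule, "message": self.message})


@dataclass
class IngestResult:
    rows: list[CurationRow] = field(default_factory=list)
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def rows_from_edges(gene: str, edges: Iterable[Edge]) -> list[CurationRow]:
    """One sheet row per assembled edge; edges from the same statement share
    a uuid, reference and evidence (provenance duplication)."""
    rows = [
        CurationRow(
            uuid=str(edge.annotations.get("uuid", "")),
            gene_key=gene,
            reference=edge.citation,
            evidence=edge.evidence_text,
            bel_statement=statement_to_bel(edge),
        )
        for edge in edges
    ]
    rows.sort(key=lambda r: (r.reference, r.uuid, r.bel_statement))
    return rows


def _mark(value: bool) -> str:
    return "x" if value else ""


def write_sheet(rows: Iterable[CurationRow], path: Union[str, Path]) -> None:
    """Write a sheet as TSV (or XLSX when the path ends in ``.xlsx``)."""
    path = Path(path)
    table = [SHEET_COLUMNS]
    for r in rows:
        table.append(
            [
                r.uuid,
                r.gene_key,
                r.reference,
                r.evidence.replace("\t", " ").replace("\n", " "),
                r.bel_statement,
                _mark(r.checked),
                _mark(r.correct),
                _mark(r.changed),
                r.error_type or "",
                r.corrected_bel or "",
                r.curator or "",
            ]
        )
    if path.suffix.lower() == ".xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "curation"
        for row in table:
            ws.append(row)
        wb.save(path)
    else:
        path.write_text("\n".join("\t".join(row) for row in table) + "\n", encoding="utf-8")


def generate_sheets(
    statements_by_gene: dict[str, list[Edge]],
    round_id: str,
    out_dir: Union[str, Path],
    combined: bool = False,
    fmt: str = "tsv",
) -> list[Path]:
    """Write per-gene curation sheets (or one combined sheet).

    Output is deterministic byte-for-byte for a fixed input: genes sorted,
    rows ordered by (citation, uuid, statement). Decision columns start
    empty.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".xlsx" if fmt == "xlsx" else ".tsv"
    paths: list[Path] = []
    if combined:
        rows: list[CurationRow] = []
        for gene in sorted(statements_by_gene):
            rows.extend(rows_from_edges(gene, statements_by_gene[gene]))
        path = out_dir / f"{round_id}_combined{suffix}"
        write_sheet(rows, path)
        return [path]
    for gene in sorted(statements_by_gene):
        safe = gene.replace(":", "_").replace("/", "_")
        path = out_dir / f"{round_id}_{safe}{suffix}"
        write_sheet(rows_from_edges(gene, statements_by_gene[gene]), path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------


class SheetSchemaError(ValueError):
    """The sheet's columns do not match the expected schema."""


def _read_table(path: Path) -> list[list[str]]:
    if path.suffix.lower() == ".xlsx":
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True)
        ws = wb.active
        return [["" if c is None else str(c) for c in row] for row in ws.iter_rows(values_only=True)]
    lines = path.read_text(encoding="utf-8").splitlines()
    return [line.split("\t") for line in lines if line.strip()]


def ingest_sheet(
    path: Union[str, Path],
    extra_error_types: Iterable[str] = (),
    machine_statements: Optional[set[tuple[str, str]]] = None,
) -> IngestResult:
    """Parse a filled curation sheet, validating the marking protocol.

    Rows violating a rule are reported as findings (with the 1-based sheet
    row number and the rule violated) and excluded from the returned valid
    rows. Unknown columns are a hard error.

    ``machine_statements`` is the set of (uuid, bel) pairs the sheet was
    generated with. When given, rows outside it are curator-added (rules
    5–6): they are accepted only when they share a known uuid, and they must
    carry Changed but never Correct. Without it, curator-added rows cannot
    be told apart from machine rows and the rule is not enforced.
    """
    path = Path(path)
    table = _read_table(path)
    if not table:
        raise SheetSchemaError("empty sheet")
    header = [h.strip() for h in table[0]]
    if header != SHEET_COLUMNS:
        unknown = [h for h in header if h not in SHEET_COLUMNS]
        if unknown:
            raise SheetSchemaError(f"unknown columns: {unknown}")
        raise SheetSchemaError(f"expected columns {SHEET_COLUMNS}, found {header}")

    vocabulary = {e.value for e in ErrorType} | set(extra_error_types)
    result = IngestResult()
    known_uuids = {uuid for uuid, _ in machine_statements} if machine_statements else set()

    for row_number, cells in enumerate(table[1:], start=2):
        cells = list(cells) + [""] * (len(SHEET_COLUMNS) - len(cells))
        record = dict(zip(SHEET_COLUMNS, (c.strip() for c in cells)))
        findings_before = len(result.findings)

        def parse_mark(column: str) -> bool:
            value = record[column]
            if value.lower() == "x":
                return True
            if value == "":
                return False
            result.findings.append(
                Finding(row_number, "mark-syntax", f"{column!r} must be 'x' or empty, found {value!r}")
            )
            return False

        checked = parse_mark("checked")
        correct = parse_mark("correct")
        changed = parse_mark("changed")
        error_type = record["error_type"] or None

        machine_origin = True
        if machine_statements is not None and (record["uuid"], record["bel"]) not in machine_statements:
            machine_origin = False
            if record["uuid"] not in known_uuids:
                result.findings.append(
                    Finding(row_number, "rule-6", "curator-added row does not share a known uuid")
                )

        if (correct or changed or error_type) and not checked:
            result.findings.append(
                Finding(row_number, "rule-1", "decision recorded without an 'x' in the Checked column")
            )
        if correct and changed:
            result.findings.append(
                Finding(row_number, "rule-2", "a row cannot be both Correct and Changed")
            )
        if error_type is not None:
            if error_type not in vocabulary:
                result.findings.append(
                    Finding(row_number, "vocabulary", f"error type {error_type!r} not in controlled vocabulary")
                )
            elif not changed and not (checked and not correct):
                result.findings.append(
                    Finding(row_number, "rule-3", "error type annotated on a row that is neither changed nor uncorrectable")
                )
        if not machine_origin:
            if correct or not changed:
                result.findings.append(
                    Finding(row_number, "rule-5", "curator-added rows must mark Changed and never Correct")
                )

        if len(result.findings) > findings_before:
            continue
        result.rows.append(
            CurationRow(
                uuid=record["uuid"],
                gene_key=record["gene"],
                reference=record["reference"],
                evidence=record["evidence"],
                bel_statement=record["bel"],
                checked=checked,
                correct=correct,
                changed=changed,
                error_type=error_type,
                corrected_bel=record["corrected_bel"] or None,
                curator=record["curator"] or None,
                machine_origin=machine_origin,
            )
        )
    return result


def classify_row(row: CurationRow) -> RowClass:
    """Total, mutually exclusive classification of a validated row."""
    if row.correct:
        return RowClass.CORRECT
    if row.changed:
        return RowClass.CHANGED
    if row.checked:
        return RowClass.UNCORRECTABLE
    return RowClass.UNCHECKED
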