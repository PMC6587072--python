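"""Curation-sheet generation, protocol validation and row classification."""

import dataclasses
import itertools

import pytest

from kgcurate.assembly import assemble
from kgcurate.corpus import ExtractedStatement, Mention, StatementType
from kgcurate.sheets import (
    SHEET_COLUMNS,
    CurationRow,
    ErrorType,
    Finding,
    RowClass,
    SheetSchemaError,
    classify_row,
    generate_sheets,
    ingest_sheet,
    rows_from_edges,
    write_sheet,
)


def stmt(uuid, subj, obj, stype=StatementType.ACTIVATION):
    return ExtractedStatement(
        uuid=uuid,
        statement_type=stype,
        subject=Mention(subj, candidates=(("HGNC", subj),)),
        object=Mention(obj, candidates=(("HGNC", obj),)),
        belief=0.9,
        evidence_text=f"{subj} regulates {obj}.",
        citation=f"pmid-{uuid}",
    )


def bundles_for(genes_statements):
    bundles = {}
    for gene, statements in genes_statements.items():
        edges = []
        for s in statements:
            edges.extend(assemble(s).edges)
        bundles[gene] = edges
    return bundles


@pytest.fixture
def two_gene_bundles():
    return bundles_for(
        {
            "HGNC:MAPT": [stmt(f"m{i}", "MAPT", f"X{i}") for i in range(3)],
            "HGNC:APP": [stmt(f"a{i}", "APP", f"Y{i}") for i in range(3)],
        }
    )


class TestGenerate:
    def test_one_sheet_per_gene_with_three_rows(self, tmp_path, two_gene_bundles):
        paths = generate_sheets(two_gene_bundles, "r1", tmp_path)
        assert len(paths) == 2
        for path in paths:
            lines = path.read_text().splitlines()
            assert lines[0] == "\t".join(SHEET_COLUMNS)
            assert len(lines) == 4  # header + 3 data rows

    def test_multi_edge_statement_duplicates_provenance(self):
        phospho = stmt("p1", "GSK3B", "MAPT", StatementType.PHOSPHORYLATION)
        rows = rows_from_edges("HGNC:MAPT", assemble(phospho).edges)
        assert len(rows) == 2
        assert {r.uuid for r in rows} == {"p1"}
        assert len({(r.reference, r.evidence) for r in rows}) == 1
        assert len({r.bel_statement for r in rows}) == 2

    def test_decision_columns_start_empty(self, tmp_path, two_gene_bundles):
        path = generate_sheets(two_gene_bundles, "r1", tmp_path)[0]
        for line in path.read_text().splitlines()[1:]:
            cells = line.split("\t")
            assert cells[5:] == ["", "", "", "", "", ""]

    def test_regeneration_is_byte_identical(self, tmp_path, two_gene_bundles):
        p1 = generate_sheets(two_gene_bundles, "r1", tmp_path / "a")
        p2 = generate_sheets(two_gene_bundles, "r1", tmp_path / "b")
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()

    def test_combined_sheet(self, tmp_path, two_gene_bundles):
        paths = generate_sheets(two_gene_bundles, "r1", tmp_path, combined=True)
        assert len(paths) == 1
        assert len(paths[0].read_text().splitlines()) == 7


class TestIngest:
    def fill(self, row: CurationRow, **kwargs) -> CurationRow:
        return dataclasses.replace(row, **kwargs)

    def write_and_ingest(self, tmp_path, rows, **kwargs):
        path = tmp_path / "sheet.tsv"
        write_sheet(rows, path)
        return ingest_sheet(path, **kwargs)

    def base_rows(self, n=4):
        return rows_from_edges(
            "HGNC:MAPT", [e for i in range(n) for e in assemble(stmt(f"u{i}", "MAPT", f"Z{i}")).edges]
        )

    def test_round_trip_preserves_provenance(self, tmp_path):
        rows = self.base_rows()
        result = self.write_and_ingest(tmp_path, rows)
        assert result.ok
        assert [(r.uuid, r.reference, r.evidence, r.bel_statement) for r in result.rows] == [
            (r.uuid, r.reference, r.evidence, r.bel_statement) for r in rows
        ]

    def test_correct_row_valid(self, tmp_path):
        rows = [self.fill(r, checked=True, correct=True) for r in self.base_rows(1)]
        result = self.write_and_ingest(tmp_path, rows)
        assert result.ok and result.rows[0].correct

    def test_changed_without_checked_cites_rule_1(self, tmp_path):
        rows = [self.fill(self.base_rows(1)[0], changed=True)]
        result = self.write_and_ingest(tmp_path, rows)
        assert [f.rule for f in result.findings] == ["rule-1"]
        assert result.rows == []

    def test_correct_and_changed_conflict(self, tmp_path):
        rows = [self.fill(self.base_rows(1)[0], checked=True, correct=True, changed=True)]
        result = self.write_and_ingest(tmp_path, rows)
        assert [f.rule for f in result.findings] == ["rule-2"]

    def test_unknown_error_type_flagged(self, tmp_path):
        rows = [self.fill(self.base_rows(1)[0], checked=True, changed=True, error_type="weird")]
        result = self.write_and_ingest(tmp_path, rows)
        assert [f.rule for f in result.findings] == ["vocabulary"]
        assert self.write_and_ingest(tmp_path, rows, extra_error_types={"weird"}).ok

    def test_non_x_mark_is_a_finding(self, tmp_path):
        path = tmp_path / "sheet.tsv"
        row = self.fill(self.base_rows(1)[0], checked=True, correct=True)
        write_sheet([row], path)
        text = path.read_text().replace("\tx\tx\t", "\tyes\tx\t")
        path.write_text(text)
        result = ingest_sheet(path)
        assert any(f.rule == "mark-syntax" for f in result.findings)

    def test_unknown_column_hard_error(self, tmp_path):
        path = tmp_path / "sheet.tsv"
        path.write_text("uuid\tgene\tbanana\n")
        with pytest.raises(SheetSchemaError, match="banana"):
            ingest_sheet(path)

    def test_curator_added_rows_must_mark_changed_only(self, tmp_path):
        rows = self.base_rows(1)
        machine = {(r.uuid, r.bel_statement) for r in rows}
        extra_ok = CurationRow(
            uuid=rows[0].uuid, gene_key=rows[0].gene_key, reference=rows[0].reference,
            evidence=rows[0].evidence, bel_statement="p(HGNC:MAPT) increases p(HGNC:NEW)",
            checked=True, changed=True,
        )
        extra_bad = dataclasses.replace(extra_ok, changed=False, correct=True)
        filled = [dataclasses.replace(rows[0], checked=True, correct=True), extra_ok]
        result = self.write_and_ingest(tmp_path, filled, machine_statements=machine)
        assert result.ok
        assert [r.machine_origin for r in result.rows] == [True, False]

        result = self.write_and_ingest(tmp_path, [extra_bad], machine_statements=machine)
        assert [f.rule for f in result.findings] == ["rule-5"]

    def test_curator_added_row_with_unknown_uuid_rejected(self, tmp_path):
        machine = {("u0", "p(HGNC:A) increases p(HGNC:B)")}
        alien = CurationRow(
            uuid="nope", gene_key="HGNC:A", reference="r", evidence="e",
            bel_statement="p(HGNC:A) increases p(HGNC:C)", checked=True, changed=True,
        )
        result = self.write_and_ingest(tmp_path, [alien], machine_statements=machine)
        assert "rule-6" in {f.rule for f in result.findings}

    def test_planted_violations_found_exactly(self, tmp_path):
        """100-row sheet with 10 planted protocol violations yields exactly
        those 10 findings."""
        rows = []
        for i in range(100):
            base = rows_from_edges("HGNC:G", assemble(stmt(f"v{i}", "G", f"T{i}")).edges)[0]
            if i % 10 == 0:  # plant: decision without Checked
                rows.append(dataclasses.replace(base, correct=True))
            else:
                rows.append(dataclasses.replace(base, checked=True, correct=(i % 2 == 0), changed=(i % 2 == 1)))
        result = self.write_and_ingest(tmp_path, rows)
        assert len(result.findings) == 10
        assert all(f.rule == "rule-1" for f in result.findings)
        assert len(result.rows) == 90

    def test_xlsx_round_trip(self, tmp_path):
        rows = [self.fill(r, checked=True, correct=True) for r in self.base_rows(2)]
        path = tmp_path / "sheet.xlsx"
        write_sheet(rows, path)
        result = ingest_sheet(path)
        assert result.ok
        assert [(r.uuid, r.bel_statement, r.correct) for r in result.rows] == [
            (r.uuid, r.bel_statement, True) for r in rows
        ]


class TestClassify:
    @pytest.mark.parametrize(
        "checked,correct,changed,expected",
        [
            (True, True, False, RowClass.CORRECT),
            (True, False, True, RowClass.CHANGED),
            (True, False, False, RowClass.UNCORRECTABLE),
            (False, False, False, RowClass.UNCHECKED),
        ],
    )
    def test_classification_table(self, checked, correct, changed, expected):
        row = CurationRow("u", "g", "r", "e", "b", checked=checked, correct=correct, changed=changed)
        assert classify_row(row) is expected

    def test_total_and_mutually_exclusive_matches_truth_table(self):
        """Classification of every flag combination equals the brute-force
        truth table: correct wins, then changed, then checked."""
        for checked, correct, changed in itertools.product([False, True], repeat=3):
            row = CurationRow("u", "g", "r", "e", "b", checked=checked, correct=correct, changed=changed)
            expected = (
                RowClass.CORRECT
                if correct
                else RowClass.CHANGED
                if changed
                else RowClass.UNCORRECTABLE
                if checked
                else RowClass.UNCHECKED
            )
            assert classify_row(row) is expected
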