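"""Reader and writer for BEL Script documents (a BEL 2.0 subset).

The dialect covers the constructs the curation workflow touches: the entity
functions ``p()``, ``g()``, ``r()``, ``m()``, ``a()``, ``complex()``,
``bp()``, ``path()``, ``act()``, the modification terms ``pmod()`` and
``var()``, and the relations increases / directlyIncreases / decreases /
directlyDecreases / regulates / association / correlation / hasVariant /
hasComponent / isA. Reactions (``rxn(...)``) are parsed as opaque nodes.
Namespaces are opaque prefixes validated only against the document's own
DEFINE NAMESPACE declarations — no live terminology lookups.

Parsing is total: unparseable lines are reported as structured
:class:`SyntaxIssue` records with line numbers, never silently dropped, and
statements whose namespaces were not declared produce warning records.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    Edge,
    Entity,
    EntityClass,
    KnowledgeGraph,
    Modification,
    ModType,
    Relation,
)

__all__ = [
    "SyntaxIssue",
    "ParseResult",
    "parse_bel_script",
    "write_bel_script",
    "entity_to_bel",
    "statement_to_bel",
    "parse_statement_line",
]


@dataclass
class SyntaxIssue:
    line: int
    column: int
    message: str
    severity: str = "error"  # "error" | "warning"

    def to_json(self) -> str:
        return json.dumps(
            {"line": self.line, "column": self.column, "message": self.message, "severity": self.severity}
        )


@dataclass
class ParseResult:
    graph: KnowledgeGraph
    errors: list[SyntaxIssue] = field(default_factory=list)
    warnings: list[SyntaxIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


_FUNC_CLASSES = {
    "p": EntityClass.PROTEIN,
    "proteinAbundance": EntityClass.PROTEIN,
    "g": EntityClass.GENE,
    "geneAbundance": EntityClass.GENE,
    "r": EntityClass.RNA,
    "rnaAbundance": EntityClass.RNA,
    "m": EntityClass.MICRORNA,
    "microRNAAbundance": EntityClass.MICRORNA,
    "a": EntityClass.ABUNDANCE,
    "abundance": EntityClass.ABUNDANCE,
    "complex": EntityClass.COMPLEX,
    "complexAbundance": EntityClass.COMPLEX,
    "bp": EntityClass.BIOLOGICAL_PROCESS,
    "biologicalProcess": EntityClass.BIOLOGICAL_PROCESS,
    "path": EntityClass.PATHOLOGY,
    "pathology": EntityClass.PATHOLOGY,
}

_CLASS_FUNCS = {
    EntityClass.PROTEIN: "p",
    EntityClass.GENE: "g",
    EntityClass.RNA: "r",
    EntityClass.MICRORNA: "m",
    EntityClass.ABUNDANCE: "a",
    EntityClass.COMPLEX: "complex",
    EntityClass.FAMILY: "p",  # families rendered as protein abundances (FPLX convention)
    EntityClass.BIOLOGICAL_PROCESS: "bp",
    EntityClass.PATHOLOGY: "path",
    EntityClass.REACTION: "rxn",
}

_RELATION_KEYWORDS = {
    "increases": Relation.INCREASES,
    "->": Relation.INCREASES,
    "directlyIncreases": Relation.DIRECTLY_INCREASES,
    "=>": Relation.DIRECTLY_INCREASES,
    "decreases": Relation.DECREASES,
    "-|": Relation.DECREASES,
    "directlyDecreases": Relation.DIRECTLY_DECREASES,
    "=|": Relation.DIRECTLY_DECREASES,
    "regulates": Relation.REGULATES,
    "reg": Relation.REGULATES,
    "association": Relation.ASSOCIATION,
    "--": Relation.ASSOCIATION,
    "correlation": Relation.CORRELATION,
    "hasVariant": Relation.HAS_VARIANT,
    "hasComponent": Relation.COMPLEX_MEMBERSHIP,
    "partOf": Relation.COMPLEX_MEMBERSHIP,
    "isA": Relation.ONTOLOGICAL,
}

_RELATION_OUT = {
    Relation.INCREASES: "increases",
    Relation.DIRECTLY_INCREASES: "directlyIncreases",
    Relation.DECREASES: "decreases",
    Relation.DIRECTLY_DECREASES: "directlyDecreases",
    Relation.REGULATES: "regulates",
    Relation.ASSOCIATION: "association",
    Relation.CORRELATION: "correlation",
    Relation.HAS_VARIANT: "hasVariant",
    Relation.COMPLEX_MEMBERSHIP: "hasComponent",
    Relation.ONTOLOGICAL: "isA",
}

_PMOD_CODES = {"Ph": ModType.PHOSPHORYLATION, "Ub": ModType.UBIQUITINATION}
_PMOD_OUT = {
    ModType.PHOSPHORYLATION: "Ph",
    ModType.UBIQUITINATION: "Ub",
    ModType.OTHER_PTM: "Other",
}


# ---------------------------------------------------------------------------
# Tokenizer / term parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<ident>[A-Za-z0-9_.\-]+)
  | (?P<punct>[():,])
  | (?P<ws>\s+)
    """,
    re.VERBOSE,
)


class _TermError(Exception):
    def __init__(self, column: int, message: str):
        super().__init__(message)
        self.column = column
        self.message = message


class _TermParser:
    def __init__(self, text: str, offset: int = 0):
        self.text = text
        self.offset = offset  # column offset within the full line
        self.tokens: list[tuple[str, str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if m is None:
                raise _TermError(offset + pos + 1, f"unexpected character {text[pos]!r}")
            kind = m.lastgroup
            if kind != "ws":
                self.tokens.append((kind, m.group(), pos))
            pos = m.end()
        self.i = 0

    def peek(self) -> Optional[tuple[str, str, int]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise _TermError(self.offset + len(self.text), "unexpected end of term")
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        kind, tok, pos = self.next()
        if tok != value:
            raise _TermError(self.offset + pos + 1, f"expected {value!r}, found {tok!r}")

    def _name(self) -> str:
        kind, tok, pos = self.next()
        if kind == "string":
            return tok[1:-1].replace('\\"', '"').replace("\\\\", "\\")
        if kind == "ident":
            return tok
        raise _TermError(self.offset + pos + 1, f"expected a name, found {tok!r}")

    def parse_term(self) -> tuple[Entity, bool]:
        """Parse one BEL term; returns (entity, activity_flag)."""
        kind, func, pos = self.next()
        if kind != "ident":
            raise _TermError(self.offset + pos + 1, f"expected a BEL function, found {func!r}")
        if func in ("act", "activity"):
            self.expect("(")
            inner, _ = self.parse_term()
            self.expect(")")
            return inner, True
        if func in ("rxn", "reaction"):
            raw = self._consume_balanced()
            return Entity(EntityClass.REACTION, label=f"rxn{raw}"), False
        if func not in _FUNC_CLASSES:
            raise _TermError(self.offset + pos + 1, f"unknown BEL function {func!r}")
        cls = _FUNC_CLASSES[func]
        self.expect("(")
        if cls is EntityClass.COMPLEX and self.peek() and self.peek()[1] in _FUNC_CLASSES:
            members = []
            while True:
                member, _ = self.parse_term()
                members.append(member)
                kind, tok, pos = self.next()
                if tok == ")":
                    break
                if tok != ",":
                    raise _TermError(self.offset + pos + 1, f"expected ',' or ')', found {tok!r}")
            return Entity(EntityClass.COMPLEX, members=tuple(members)), False
        namespace = self._name()
        self.expect(":")
        name = self._name()
        variants = []
        while True:
            kind, tok, pos = self.next()
            if tok == ")":
                break
            if tok != ",":
                raise _TermError(self.offset + pos + 1, f"expected ',' or ')', found {tok!r}")
            variants.append(self._parse_variant())
        return (
            Entity(cls, namespace=namespace, identifier=name, label=name, variants=tuple(variants)),
            False,
        )

    def _parse_variant(self) -> Modification:
        kind, func, pos = self.next()
        if func == "pmod":
            self.expect("(")
            code = self._name()
            residue = position = None
            nxt = self.next()
            if nxt[1] == ",":
                residue = self._name()
                nxt = self.next()
                if nxt[1] == ",":
                    pos_name = self._name()
                    try:
                        position = int(pos_name)
                    except ValueError:
                        raise _TermError(self.offset + nxt[2] + 1, f"invalid pmod position {pos_name!r}")
                    nxt = self.next()
            if nxt[1] != ")":
                raise _TermError(self.offset + nxt[2] + 1, f"expected ')', found {nxt[1]!r}")
            mod_type = _PMOD_CODES.get(code, ModType.OTHER_PTM)
            return Modification(mod_type, residue=residue, position=position)
        if func == "var":
            self.expect("(")
            desc = self._name()
            self.expect(")")
            return Modification(ModType.SEQUENCE_VARIANT, residue=desc)
        raise _TermError(self.offset + pos + 1, f"unknown variant term {func!r}")

    def _consume_balanced(self) -> str:
        """Consume a parenthesized token run verbatim (opaque reactions)."""
        kind, tok, start = self.next()
        if tok != "(":
            raise _TermError(self.offset + start + 1, "expected '('")
        depth = 1
        end = start + 1
        while depth:
            kind, tok, pos = self.next()
            if tok == "(":
                depth += 1
            elif tok == ")":
                depth -= 1
            end = pos + len(tok)
        return self.text[start:end]

    def at_end(self) -> bool:
        return self.i >= len(self.tokens)


def _find_relation(line: str) -> Optional[tuple[int, int, Relation]]:
    """Locate the top-level relation keyword (outside parentheses/strings)."""
    depth = 0
    i = 0
    n = len(line)
    while i < n:
        c = line[i]
        if c == '"':
            i += 1
            while i < n and line[i] != '"':
                i += 2 if line[i] == "\\" else 1
            i += 1
            continue
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
        elif depth == 0 and c == " ":
            m = re.match(r"\s*(\S+)\s", line[i:])
            if m and m.group(1) in _RELATION_KEYWORDS:
                start = i + m.start(1)
                return start, start + len(m.group(1)), _RELATION_KEYWORDS[m.group(1)]
        i += 1
    return None


def parse_statement_line(line: str) -> tuple[Entity, Relation, Entity, bool, bool]:
    """Parse a single BEL statement line.

    Returns (subject, relation, object, subject_activity, object_activity).
    Raises ValueError with a column-bearing message on malformed input.
    """
    loc = _find_relation(line)
    if loc is None:
        raise _SyntaxError(1, "no relation keyword found in statement")
    start, end, relation = loc
    try:
        sp = _TermParser(line[:start].strip())
        subject, s_act = sp.parse_term()
        if not sp.at_end():
            raise _TermError(start, "trailing tokens after subject term")
        op = _TermParser(line[end:].strip(), offset=end)
        obj, o_act = op.parse_term()
        if not op.at_end():
            raise _TermError(end, "trailing tokens after object term")
    except _TermError as exc:
        raise _SyntaxError(exc.column, exc.message) from exc
    return subject, relation, obj, s_act, o_act


class _SyntaxError(Exception):
    def __init__(self, column: int, message: str):
        super().__init__(message)
        self.column = column
        self.message = message


# ---------------------------------------------------------------------------
# Document parser
# ---------------------------------------------------------------------------

_SET_DOC_RE = re.compile(r'^SET\s+DOCUMENT\s+(\w+)\s*=\s*"((?:[^"\\]|\\.)*)"\s*$')
_DEFINE_NS_RE = re.compile(r'^DEFINE\s+NAMESPACE\s+(\S+)\s+AS\s+(?:URL|PATTERN)\s+"((?:[^"\\]|\\.)*)"\s*$')
_DEFINE_ANNO_RE = re.compile(r'^DEFINE\s+ANNOTATION\s+(\S+)\s+AS\s+.*$')
_SET_RE = re.compile(r'^SET\s+(\w+)\s*=\s*(.*)$')
_UNSET_RE = re.compile(r'^UNSET\s+(\w+|ALL)\s*$')


def _unquote(s: str) -> str:
    return s[1:-1].replace('\\"', '"').replace("\\\\", "\\")


def parse_bel_script(text: str) -> ParseResult:
    """Parse a BEL Script document into a knowledge graph.

    Every statement's active SET annotations are captured on its edge.
    Unparseable lines are reported in ``result.errors`` with their line
    number; statements using namespaces that the document never declares
    produce warnings. SET/UNSET blocks must be well-nested in the sense that
    UNSET only names annotations currently set.
    """
    kg = KnowledgeGraph()
    result = ParseResult(graph=kg)
    declared: dict[str, str] = {}
    active: dict[str, str] = {}
    citation = ""
    citation_db = "PubMed"
    warned_namespaces: set[str] = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("//"):
            continue

        m = _SET_DOC_RE.match(line)
        if m:
            key, value = m.group(1), m.group(2)
            if key.lower() in ("name", "version"):
                kg.document_metadata[key.lower()] = value
            continue
        m = _DEFINE_NS_RE.match(line)
        if m:
            declared[m.group(1)] = m.group(2)
            kg.document_metadata["namespaces"][m.group(1)] = m.group(2)
            continue
        if _DEFINE_ANNO_RE.match(line):
            continue
        m = _SET_RE.match(line)
        if m:
            key, value = m.group(1), m.group(2).strip()
            if key == "Citation":
                inner = value.strip()
                if not (inner.startswith("{") and inner.endswith("}")):
                    result.errors.append(SyntaxIssue(lineno, 1, "malformed Citation (expected {...})"))
                    continue
                parts = re.findall(r'"((?:[^"\\]|\\.)*)"', inner)
                if not parts:
                    result.errors.append(SyntaxIssue(lineno, 1, "empty Citation"))
                    continue
                citation_db = parts[0] if len(parts) > 1 else "PubMed"
                citation = parts[-1]
            elif value.startswith('"') and value.endswith('"') and len(value) >= 2:
                active[key] = _unquote(value)
            else:
                result.errors.append(SyntaxIssue(lineno, 1, f"malformed SET value for {key!r}"))
            continue
        m = _UNSET_RE.match(line)
        if m:
            key = m.group(1)
            if key == "ALL":
                active.clear()
                citation = ""
            elif key == "Citation":
                citation = ""
            elif key in active:
                del active[key]
            else:
                result.warnings.append(
                    SyntaxIssue(lineno, 1, f"UNSET of annotation {key!r} that is not set", severity="warning")
                )
            continue

        # Anything else must be a statement line.
        try:
            subject, relation, obj, s_act, o_act = parse_statement_line(line)
        except _SyntaxError as exc:
            result.errors.append(SyntaxIssue(lineno, exc.column, exc.message))
            continue

        annotations = {k: v for k, v in active.items() if k != "Evidence"}
        if s_act:
            annotations["_subject_activity"] = "true"
        if o_act:
            annotations["_object_activity"] = "true"
        if citation_db != "PubMed":
            annotations["_citation_db"] = citation_db
        edge = Edge(
            subject=subject,
            object=obj,
            relation=relation,
            evidence_text=active.get("Evidence", ""),
            citation=citation,
            annotations=annotations,
        )
        for ns in KnowledgeGraph.from_edges([edge]).namespaces_used():
            if ns not in declared and ns not in warned_namespaces:
                warned_namespaces.add(ns)
                result.warnings.append(
                    SyntaxIssue(lineno, 1, f"namespace {ns!r} used but not declared", severity="warning")
                )
        kg.add_edge(edge)

    return result


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------


def _quote(name: str) -> str:
    if re.fullmatch(r"[A-Za-z0-9_]+", name):
        return name
    escaped = name.replace("\\", "\\\\").replace('"', '\\"')
    return f'"{escaped}"'


def _mod_to_bel(mod: Modification) -> str:
    if mod.mod_type is ModType.SEQUENCE_VARIANT:
        return f"var({_quote(mod.residue or '?')})"
    parts = [_PMOD_OUT[mod.mod_type]]
    if mod.residue:
        parts.append(mod.residue)
    if mod.position is not None:
        parts.append(str(mod.position))
    return f"pmod({', '.join(parts)})"


def entity_to_bel(entity: Entity) -> str:
    if entity.entity_class is EntityClass.REACTION:
        return entity.label or "rxn()"
    func = _CLASS_FUNCS[entity.entity_class]
    if entity.members:
        inner = ", ".join(sorted(entity_to_bel(m) for m in entity.members))
        return f"complex({inner})"
    args = [f"{entity.namespace}:{_quote(entity.identifier)}"]
    args.extend(_mod_to_bel(v) for v in entity.variants)
    return f"{func}({', '.join(args)})"


def statement_to_bel(edge: Edge) -> str:
    subj = entity_to_bel(edge.subject)
    obj = entity_to_bel(edge.object)
    if edge.annotations.get("_subject_activity"):
        subj = f"act({subj})"
    if edge.annotations.get("_object_activity"):
        obj = f"act({obj})"
    return f"{subj} {_RELATION_OUT[edge.relation]} {obj}"


def _escape(value: str) -> str:
    return value.replace("\\", "\\\\").replace('"', '\\"').replace("\n", " ")


def write_bel_script(kg: KnowledgeGraph) -> str:
    """Serialize a knowledge graph as a BEL Script document.

    Output is deterministic: namespace declarations are sorted, statements
    are sorted by (citation, statement text, evidence), and every statement
    sits in its own SET Citation / SET Evidence block, so writing is
    idempotent across parse/write round trips.
    """
    meta = kg.document_metadata
    lines = [
        f'SET DOCUMENT Name = "{_escape(meta.get("name") or "Untitled")}"',
        f'SET DOCUMENT Version = "{_escape(meta.get("version") or "0.0.0")}"',
        "",
    ]
    namespaces = dict(meta.get("namespaces", {}))
    for ns in sorted(kg.namespaces_used() - set(namespaces)):
        namespaces[ns] = f"https://example.org/namespaces/{ns.lower()}.belns"
    for ns in sorted(namespaces):
        lines.append(f'DEFINE NAMESPACE {ns} AS URL "{_escape(namespaces[ns])}"')
    lines.append("")

    def sort_key(edge: Edge):
        return (edge.citation, statement_to_bel(edge), edge.evidence_text)

    for edge in sorted(kg.edges(), key=sort_key):
        db = edge.annotations.get("_citation_db", "PubMed")
        lines.append(f'SET Citation = {{"{_escape(db)}", "{_escape(edge.citation)}"}}')
        lines.append(f'SET Evidence = "{_escape(edge.evidence_text)}"')
        public = sorted(
            (k, v) for k, v in edge.annotations.items() if not k.startswith("_")
        )
        for key, value in public:
            lines.append(f'SET {key} = "{_escape(str(value))}"')
        lines.append(statement_to_bel(edge))
        for key, _ in reversed(public):
            lines.append(f"UNSET {key}")
        lines.append("UNSET Evidence")
        lines.append("UNSET Citation")
        lines.append("")

    return "\n".join(lines)
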