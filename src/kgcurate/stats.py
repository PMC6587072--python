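"""Evaluation statistics for a curation exercise.

Given the ingested curation rows, this module computes the headline numbers
of a curation round: how many evaluated statements were correct as
extracted, how many needed manual correction, how many were uncorrectable,
and the recovery rate — the fraction of evaluated statements that end up
usable (correct as-is or successfully fixed):

    recovery = (n_correct + n_changed) / n_evaluated

Unchecked rows never enter any denominator: only rows a curator actually
evaluated count. Percentages are reported to one decimal place; internal
values keep full precision. Throughput is edges per minute over the hours a
round took.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from scipy import stats as _scipy_stats

from .sheets import CurationRow, RowClass, classify_row

__all__ = [
    "CurationReport",
    "GroupComparison",
    "summarize",
    "throughput",
    "error_profile",
    "compare_groups",
]


def _pct(numerator: int, denominator: int) -> Optional[float]:
    return None if denominator == 0 else 100.0 * numerator / denominator


def _round1(value: Optional[float]) -> Optional[float]:
    return None if value is None else round(value, 1)


@dataclass
class CurationReport:
    n_evaluated: int
    n_correct: int
    n_changed: int
    n_uncorrectable: int
    n_unchecked: int = 0
    per_gene_accuracy: dict = field(default_factory=dict)
    per_gene_recovery: dict = field(default_factory=dict)
    error_type_counts: dict = field(default_factory=dict)
    edges_per_minute: Optional[float] = None

    # -- full-precision fractions -----------------------------------------

    @property
    def defined(self) -> bool:
        """Percentages are undefined (not NaN) when nothing was evaluated."""
        return self.n_evaluated > 0

    @property
    def pct_correct_raw(self) -> Optional[float]:
        return _pct(self.n_correct, self.n_evaluated)

    @property
    def pct_changed_raw(self) -> Optional[float]:
        return _pct(self.n_changed, self.n_evaluated)

    @property
    def pct_uncorrectable_raw(self) -> Optional[float]:
        return _pct(self.n_uncorrectable, self.n_evaluated)

    @property
    def recovery_pct_raw(self) -> Optional[float]:
        return _pct(self.n_correct + self.n_changed, self.n_evaluated)

    # -- reported values (1 decimal) ---------------------------------------

    @property
    def pct_correct(self) -> Optional[float]:
        return _round1(self.pct_correct_raw)

    @property
    def pct_changed(self) -> Optional[float]:
        return _round1(self.pct_changed_raw)

    @property
    def pct_uncorrectable(self) -> Optional[float]:
        return _round1(self.pct_uncorrectable_raw)

    @property
    def recovery_pct(self) -> Optional[float]:
        return _round1(self.recovery_pct_raw)

    def to_dict(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "n_correct": self.n_correct,
            "n_changed": self.n_changed,
            "n_uncorrectable": self.n_uncorrectable,
            "n_unchecked": self.n_unchecked,
            "pct_correct": self.pct_correct,
            "pct_changed": self.pct_changed,
            "pct_uncorrectable": self.pct_uncorrectable,
            "recovery_pct": self.recovery_pct,
            "per_gene_accuracy": {k: _round1(v) for k, v in self.per_gene_accuracy.items()},
            "per_gene_recovery": {k: _round1(v) for k, v in self.per_gene_recovery.items()},
            "error_type_counts": dict(self.error_type_counts),
            "edges_per_minute": self.edges_per_minute,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def to_text(self) -> str:
        if not self.defined:
            return "No rows evaluated; percentages undefined.\n"
        lines = [
            f"Evaluated statements : {self.n_evaluated}",
            f"  correct            : {self.n_correct} ({self.pct_correct}%)",
            f"  changed            : {self.n_changed} ({self.pct_changed}%)",
            f"  uncorrectable      : {self.n_uncorrectable} ({self.pct_uncorrectable}%)",
            f"Recovery rate        : {self.recovery_pct}%",
        ]
        if self.edges_per_minute is not None:
            lines.append(f"Throughput           : {self.edges_per_minute} edges/min")
        if self.error_type_counts:
            lines.append("Error types:")
            for code, count in sorted(self.error_type_counts.items(), key=lambda kv: (-kv[1], kv[0])):
                lines.append(f"  {code:<28s}: {count}")
        return "\n".join(lines) + "\n"


def summarize(rows: Iterable[CurationRow], hours: Optional[float] = None) -> CurationReport:
    """Aggregate curation rows into a report.

    Per-gene accuracy is correct/evaluated within the gene; per-gene
    recovery is (correct+changed)/evaluated. With ``hours`` given, the
    throughput over recovered (correct+changed) rows is included.
    """
    counts = {cls: 0 for cls in RowClass}
    per_gene: dict[str, dict[RowClass, int]] = {}
    error_counts: dict[str, int] = {}
    for row in rows:
        cls = classify_row(row)
        counts[cls] += 1
        if cls is not RowClass.UNCHECKED:
            gene_counts = per_gene.setdefault(row.gene_key, {c: 0 for c in RowClass})
            gene_counts[cls] += 1
            if row.error_type:
                error_counts[row.error_type] = error_counts.get(row.error_type, 0) + 1

    n_correct = counts[RowClass.CORRECT]
    n_changed = counts[RowClass.CHANGED]
    n_uncorrectable = counts[RowClass.UNCORRECTABLE]
    n_evaluated = n_correct + n_changed + n_uncorrectable

    per_gene_accuracy = {}
    per_gene_recovery = {}
    for gene, gc in per_gene.items():
        evaluated = gc[RowClass.CORRECT] + gc[RowClass.CHANGED] + gc[RowClass.UNCORRECTABLE]
        per_gene_accuracy[gene] = _pct(gc[RowClass.CORRECT], evaluated)
        per_gene_recovery[gene] = _pct(gc[RowClass.CORRECT] + gc[RowClass.CHANGED], evaluated)

    report = CurationReport(
        n_evaluated=n_evaluated,
        n_correct=n_correct,
        n_changed=n_changed,
        n_uncorrectable=n_uncorrectable,
        n_unchecked=counts[RowClass.UNCHECKED],
        per_gene_accuracy=per_gene_accuracy,
        per_gene_recovery=per_gene_recovery,
        error_type_counts=error_counts,
    )
    if hours is not None:
        report.edges_per_minute = throughput(n_correct + n_changed, hours)
    return report


def throughput(n_edges: int, hours: float) -> float:
    """Curation rate in edges per minute, to two decimals."""
    if hours <= 0:
        raise ValueError("hours must be positive")
    return round(n_edges / (hours * 60.0), 2)


def error_profile(rows: Iterable[CurationRow]) -> dict[str, dict]:
    """Counts and fractions of annotated error types.

    Fractions are over changed + uncorrectable rows (the rows that *could*
    carry an error annotation); they sum to at most 1 because not every such
    row is annotated.
    """
    rows = list(rows)
    denominator = sum(
        1 for r in rows if classify_row(r) in (RowClass.CHANGED, RowClass.UNCORRECTABLE)
    )
    counts: dict[str, int] = {}
    for row in rows:
        if row.error_type and classify_row(row) is not RowClass.UNCHECKED:
            counts[row.error_type] = counts.get(row.error_type, 0) + 1
    return {
        code: {"count": count, "fraction": (count / denominator) if denominator else 0.0}
        for code, count in sorted(counts.items())
    }


@dataclass(frozen=True)
class GroupComparison:
    top_genes: tuple[str, ...]
    bottom_genes: tuple[str, ...]
    top_mean: float
    bottom_mean: float
    t_statistic: float
    p_value: float
    welch: bool


def compare_groups(
    per_gene_accuracy: dict[str, float],
    per_gene_effort: dict[str, float],
    k: int = 20,
    welch: bool = True,
) -> GroupComparison:
    """Compare curation effort between the k most and k least accurately
    extracted genes with a two-sample t-test.

    Welch's unequal-variance variant is the default; ``welch=False`` gives
    the pooled-variance Student test. Ties in accuracy break
    lexicographically by gene key for determinism.
    """
    genes = [g for g in per_gene_accuracy if g in per_gene_effort and per_gene_accuracy[g] is not None]
    if k > len(genes) // 2:
        raise ValueError(f"k={k} exceeds half the number of genes ({len(genes)})")
    if k < 2:
        raise ValueError("group size must be at least 2")
    ordered = sorted(genes, key=lambda g: (-per_gene_accuracy[g], g))
    top = tuple(ordered[:k])
    bottom = tuple(ordered[-k:])
    top_effort = [per_gene_effort[g] for g in top]
    bottom_effort = [per_gene_effort[g] for g in bottom]
    t, p = _scipy_stats.ttest_ind(top_effort, bottom_effort, equal_var=not welch)
    return GroupComparison(
        top_genes=top,
        bottom_genes=bottom,
        top_mean=float(sum(top_effort) / k),
        bottom_mean=float(sum(bottom_effort) / k),
        t_statistic=float(t),
        p_value=float(p),
        welch=welch,
    )
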