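"""Curation evaluation arithmetic: accuracy, recovery, errors, throughput."""

import math
import random

import numpy as np
import pytest

from kgcurate.sheets import CurationRow, ErrorType
from kgcurate.stats import compare_groups, error_profile, summarize, throughput


def row(uuid="u", gene="HGNC:G", checked=True, correct=False, changed=False, error_type=None):
    return CurationRow(uuid, gene, "ref", "ev", "bel", checked=checked, correct=correct,
                       changed=changed, error_type=error_type)


def rows_with_counts(n_correct, n_changed, n_uncorrectable, n_unchecked=0, gene="HGNC:G"):
    rows = []
    rows += [row(f"c{i}", gene, correct=True) for i in range(n_correct)]
    rows += [row(f"h{i}", gene, changed=True) for i in range(n_changed)]
    rows += [row(f"u{i}", gene) for i in range(n_uncorrectable)]
    rows += [row(f"n{i}", gene, checked=False) for i in range(n_unchecked)]
    return rows


class TestSummarize:
    def test_published_scale_counts_reproduce_percentages(self):
        """2989 evaluated = 917 correct + 1454 changed + 618 uncorrectable
        gives 30.7 / 48.6 / 20.7 and recovery 79.3 at one decimal."""
        report = summarize(rows_with_counts(917, 1454, 618))
        assert report.n_evaluated == 2989
        assert report.pct_correct == 30.7
        assert report.pct_changed == 48.6
        assert report.pct_uncorrectable == 20.7
        assert report.recovery_pct == 79.3

    def test_all_correct(self):
        report = summarize(rows_with_counts(10, 0, 0))
        assert report.pct_correct == 100.0
        assert report.recovery_pct == 100.0
        assert report.per_gene_accuracy == {"HGNC:G": 100.0}

    def test_zero_evaluated_undefined_not_nan(self):
        report = summarize(rows_with_counts(0, 0, 0, n_unchecked=5))
        assert not report.defined
        assert report.pct_correct is None and report.recovery_pct is None
        assert report.n_unchecked == 5
        assert "undefined" in report.to_text()

    def test_unchecked_rows_never_in_denominators(self):
        with_unchecked = summarize(rows_with_counts(3, 4, 3, n_unchecked=90))
        without = summarize(rows_with_counts(3, 4, 3))
        assert with_unchecked.n_evaluated == without.n_evaluated == 10
        assert with_unchecked.pct_correct == without.pct_correct

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_count_conservation_and_percent_sum(self, seed):
        rng = random.Random(seed)
        rows = rows_with_counts(rng.randint(1, 50), rng.randint(0, 50), rng.randint(0, 50), rng.randint(0, 20))
        report = summarize(rows)
        assert report.n_correct + report.n_changed + report.n_uncorrectable == report.n_evaluated
        assert math.isclose(
            report.pct_correct_raw + report.pct_changed_raw + report.pct_uncorrectable_raw, 100.0
        )
        assert math.isclose(
            report.recovery_pct_raw,
            100.0 * (report.n_correct + report.n_changed) / report.n_evaluated,
        )

    def test_permutation_invariant(self):
        rows = rows_with_counts(5, 7, 3, 2)
        shuffled = rows[:]
        random.Random(1).shuffle(shuffled)
        assert summarize(rows).to_dict() == summarize(shuffled).to_dict()

    def test_per_gene_accuracy_recovers_planted_rate(self):
        """Genes with a planted 35% correct rate: estimates land inside the
        binomial 95% interval at n=200 rows per gene."""
        rng = np.random.default_rng(42)
        rows = []
        p = 0.35
        for g in range(5):
            gene = f"HGNC:G{g}"
            for i in range(200):
                if rng.random() < p:
                    rows.append(row(f"{gene}-{i}", gene, correct=True))
                else:
                    rows.append(row(f"{gene}-{i}", gene, changed=True))
        report = summarize(rows)
        half_width = 1.96 * math.sqrt(p * (1 - p) / 200) * 100
        for gene, accuracy in report.per_gene_accuracy.items():
            assert abs(accuracy - 35.0) <= half_width

    def test_per_gene_recovery(self):
        rows = rows_with_counts(2, 2, 1, gene="HGNC:A") + rows_with_counts(0, 1, 3, gene="HGNC:B")
        report = summarize(rows)
        assert report.per_gene_recovery["HGNC:A"] == pytest.approx(80.0)
        assert report.per_gene_recovery["HGNC:B"] == pytest.approx(25.0)


class TestThroughput:
    def test_published_scale_rate(self):
        """17002 edges in 80 hours is 3.54 edges per minute."""
        assert throughput(17002, 80) == 3.54

    def test_unit_rate(self):
        assert throughput(60, 1) == 1.00

    @pytest.mark.parametrize("seed", [0, 1])
    def test_rate_doubles_when_hours_halve(self, seed):
        rng = random.Random(seed)
        for _ in range(20):
            n = rng.randint(100, 100000)
            h = rng.uniform(1, 100)
            assert throughput(n, h / 2) == pytest.approx(2 * throughput(n, h), abs=0.05)

    def test_nonpositive_hours_error(self):
        with pytest.raises(ValueError):
            throughput(10, 0)
        with pytest.raises(ValueError):
            throughput(10, -1)


class TestErrorProfile:
    def test_empty_when_no_annotations(self):
        assert error_profile(rows_with_counts(3, 0, 2)) == {}

    def test_planted_counts_exact(self):
        rows = [row(f"n{i}", changed=True, error_type=ErrorType.NER_WRONG_ENTITY.value) for i in range(3)]
        rows += [row("s0", changed=True, error_type=ErrorType.SUBJECT_OBJECT_SWAP.value)]
        rows += [row(f"x{i}", changed=True) for i in range(2)]
        profile = error_profile(rows)
        assert profile[ErrorType.NER_WRONG_ENTITY.value]["count"] == 3
        assert profile[ErrorType.SUBJECT_OBJECT_SWAP.value]["count"] == 1
        assert profile[ErrorType.NER_WRONG_ENTITY.value]["fraction"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_fractions_sum_at_most_one(self, seed):
        rng = random.Random(seed)
        codes = [e.value for e in ErrorType]
        rows = []
        for i in range(100):
            annotated = rng.random() < 0.6
            rows.append(
                row(f"r{i}", changed=annotated, error_type=rng.choice(codes) if annotated else None)
            )
        profile = error_profile(rows)
        assert sum(v["fraction"] for v in profile.values()) <= 1.0 + 1e-9


class TestCompareGroups:
    def test_identical_groups_t_zero_p_one(self):
        accuracy = {f"g{i}": float(i) for i in range(10)}
        effort = {g: 2.0 for g in accuracy}
        result = compare_groups(accuracy, effort, k=5)
        assert result.t_statistic == pytest.approx(0.0, abs=1e-9) or math.isnan(result.t_statistic)
        if not math.isnan(result.p_value):
            assert result.p_value > 0.99

    def test_planted_effort_gap_detected(self):
        """Low-accuracy genes cost ~1.5 min more per statement: with n=20 a
        two-sample t-test flags the gap at p < 0.01."""
        rng = np.random.default_rng(7)
        accuracy = {}
        effort = {}
        for i in range(20):
            accuracy[f"hi{i}"] = 80.0 + rng.normal(0, 2)
            effort[f"hi{i}"] = max(0.1, rng.normal(2.0, 0.5))
        for i in range(20):
            accuracy[f"lo{i}"] = 20.0 + rng.normal(0, 2)
            effort[f"lo{i}"] = max(0.1, rng.normal(3.5, 0.5))
        result = compare_groups(accuracy, effort, k=20)
        assert result.p_value < 0.01
        assert result.bottom_mean > result.top_mean

    def test_t_statistic_matches_closed_form_on_hand_data(self):
        """Welch t on a 5+5 dataset recomputed from the textbook formula."""
        top = [1.0, 1.2, 0.9, 1.1, 1.0]
        bottom = [2.0, 2.5, 1.8, 2.2, 2.1]
        accuracy = {f"t{i}": 90.0 + i for i in range(5)}
        accuracy.update({f"b{i}": 10.0 + i for i in range(5)})
        effort = {f"t{i}": top[i] for i in range(5)}
        effort.update({f"b{i}": bottom[i] for i in range(5)})
        result = compare_groups(accuracy, effort, k=5)
        m1, m2 = np.mean(top), np.mean(bottom)
        v1, v2 = np.var(top, ddof=1), np.var(bottom, ddof=1)
        expected_t = (m1 - m2) / math.sqrt(v1 / 5 + v2 / 5)
        assert result.t_statistic == pytest.approx(expected_t, rel=1e-9)

    def test_group_size_validation(self):
        accuracy = {f"g{i}": float(i) for i in range(6)}
        effort = {g: 1.0 for g in accuracy}
        with pytest.raises(ValueError):
            compare_groups(accuracy, effort, k=4)
        with pytest.raises(ValueError):
            compare_groups(accuracy, effort, k=1)
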