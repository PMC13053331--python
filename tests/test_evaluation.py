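"""Concordance metrics, PBMC logic, error rates, correlation, stats harness."""

import numpy as np
import pytest
from scipy import stats as scipy_stats

from cytoreport.errors import SchemaError, UsageError
from cytoreport.evaluation import (
    DEFAULT_PBMC_RULE,
    PbmcOutcome,
    ReferenceStandard,
    UNDEFINED,
    benjamini_hochberg,
    compare_methods,
    error_rate,
    evaluate_report,
    format_error_rate,
    pbmc_check,
    pbmc_expected,
    prevalence_correlation,
)
from cytoreport.extraction import ExtractedStatement, extract_report_statements
from cytoreport.panel import Degree, Direction, Quantifier, panel_abnormalities
from cytoreport.reporting import render_report
from conftest import make_abnormal


def _stmt(cell, direction, degree, quantifier):
    return ExtractedStatement(
        cell_type=cell,
        direction=Direction(direction),
        degree=Degree(degree),
        quantifier=Quantifier(quantifier),
    )


@pytest.fixture()
def six_abnormal_panel(schema, normal_panel):
    """Six distinct families decreased mildly (counts)."""
    over = {}
    for fam in ["CD3", "CD4", "CD8", "NAIVE", "TOTAL_MEMORY", "CD21POS"]:
        r = schema.range_for(f"{fam}_CT", 37.0)
        over[f"{fam}_CT"] = r.lower * 0.9  # d = 0.10 -> mild decreased
    return make_abnormal(schema, normal_panel, **over)


class TestEvaluateReport:
    def test_commenting_three_of_six_gives_half(self, schema, six_abnormal_panel):
        statements = [
            _stmt(f, "decreased", "mild", "count") for f in ["CD3", "CD4", "CD8"]
        ]
        rec = evaluate_report(statements, six_abnormal_panel, schema)
        assert rec.comment_rate == 0.5
        assert rec.n_omitted == 3 and rec.n_unsupported == 0

    def test_oracle_report_scores_perfectly(self, schema, cohort, aliases):
        panel = next(p for p in cohort if panel_abnormalities(p, schema))
        report = render_report(panel, schema, "harmonized", aliases)
        rec = evaluate_report(extract_report_statements(report, aliases), panel, schema)
        assert rec.comment_rate == 1.0
        assert rec.direction_accuracy == 1.0
        assert rec.degree_accuracy == 1.0
        assert rec.quantifier_accuracy == 1.0
        assert rec.n_unsupported == 0 and rec.n_omitted == 0

    def test_known_edits_predict_metric_deficits(self, schema, normal_panel):
        """Five abnormalities; 2 omitted, 1 direction-flipped: comment rate
        3/5 and direction accuracy 2/3."""
        fams = ["CD3", "CD4", "CD8", "NAIVE", "CD21POS"]
        over = {f + "_CT": schema.range_for(f + "_CT", 37.0).lower * 0.9 for f in fams}
        panel = make_abnormal(schema, normal_panel, **over)
        statements = [
            _stmt("CD3", "increased", "mild", "count"),  # flipped
            _stmt("CD4", "decreased", "mild", "count"),
            _stmt("CD8", "decreased", "mild", "count"),
        ]
        rec = evaluate_report(statements, panel, schema)
        assert rec.comment_rate == pytest.approx(3 / 5)
        assert rec.direction_accuracy == pytest.approx(2 / 3)

    def test_unsupported_statement_is_false_positive(self, schema, normal_panel):
        rec = evaluate_report(
            [_stmt("NK", "increased", "mild", "count")], normal_panel, schema
        )
        assert rec.n_unsupported == 1
        assert rec.comment_rate is UNDEFINED  # no reference abnormality

    def test_unspecified_degree_counts_as_comment_only(self, schema, normal_panel):
        panel = make_abnormal(
            schema, normal_panel, CD4_CT=schema.range_for("CD4_CT", 37.0).lower * 0.9
        )
        rec = evaluate_report(
            [_stmt("CD4", "decreased", "unspecified", "count")], panel, schema
        )
        assert rec.comment_rate == 1.0
        assert rec.degree_accuracy is UNDEFINED

    def test_both_statement_matches_either_twin(self, schema, normal_panel):
        panel = make_abnormal(
            schema,
            normal_panel,
            CD4_CT=schema.range_for("CD4_CT", 37.0).lower * 0.9,
            CD4_PCT=schema.range_for("CD4_PCT", 37.0).lower * 0.9,
        )
        rec = evaluate_report([_stmt("CD4", "decreased", "mild", "both")], panel, schema)
        assert rec.comment_rate == 1.0 and rec.quantifier_accuracy == 1.0

    def test_quantifier_mismatch_detected(self, schema, normal_panel):
        panel = make_abnormal(
            schema, normal_panel, CD4_CT=schema.range_for("CD4_CT", 37.0).lower * 0.9
        )
        rec = evaluate_report([_stmt("CD4", "decreased", "mild", "both")], panel, schema)
        # claims count+percent but only the count twin is abnormal
        assert rec.quantifier_accuracy == 0.0
        assert rec.n_unsupported == 1

    def test_reference_report_standard_requires_statements(self, schema, normal_panel):
        with pytest.raises(UsageError):
            evaluate_report([], normal_panel, schema, ReferenceStandard.REFERENCE_REPORT)

    def test_standards_coincide_when_reference_comments_everything(
        self, schema, cohort, aliases
    ):
        """With the uncorrupted reference report as the standard, lab-value
        and reference-report metrics agree on every cell type."""
        for panel in cohort[:20]:
            report = render_report(panel, schema, "harmonized", aliases)
            statements = extract_report_statements(report, aliases)
            lab = evaluate_report(statements, panel, schema, ReferenceStandard.LAB_VALUES)
            ref = evaluate_report(
                statements,
                panel,
                schema,
                ReferenceStandard.REFERENCE_REPORT,
                reference_statements=statements,
            )
            assert lab.per_cell == ref.per_cell
            assert lab.quantifier_correct == ref.quantifier_correct


class TestPbmc:
    def test_default_rule(self, schema, normal_panel):
        assert pbmc_expected(normal_panel, schema) is False
        low_cd19 = make_abnormal(schema, normal_panel, CD19_CT=50.0)
        assert pbmc_expected(low_cd19, schema) is True

    def test_missing_rule_analyte_is_schema_error(self, schema, normal_panel):
        from cytoreport.evaluation import PbmcClause, PbmcRule

        rule = PbmcRule(any_of=[PbmcClause(analyte_id="CD57_CT")])
        with pytest.raises(SchemaError):
            pbmc_expected(normal_panel, schema, rule)

    def test_matches_brute_force_predicate(self, schema, cohort):
        """Over random panels the rule equals a direct range comparison on
        the CD19+/CD20+ absolute counts."""
        for panel in cohort:
            brute = any(
                not (
                    schema.range_for(aid, panel.patient_age).lower
                    <= panel.values[aid]
                    <= schema.range_for(aid, panel.patient_age).upper
                )
                for aid in ("CD19_CT", "CD20_CT")
            )
            assert pbmc_expected(panel, schema) == brute

    def test_check_outcomes(self, schema, normal_panel, cohort, aliases):
        report = render_report(normal_panel, schema, "harmonized", aliases)
        assert pbmc_check(report, normal_panel, schema) == PbmcOutcome.MATCH
        low = make_abnormal(schema, normal_panel, CD19_CT=50.0)
        # report for the normal panel lacks the expected PBMC comment
        assert pbmc_check(report, low, schema) == PbmcOutcome.MISSING_COMMENT
        low_report = render_report(low, schema, "harmonized", aliases)
        assert pbmc_check(low_report, low, schema) == PbmcOutcome.MATCH
        assert pbmc_check(low_report, normal_panel, schema) == PbmcOutcome.UNSUPPORTED_COMMENT


class TestErrorRate:
    @pytest.mark.parametrize(
        "errors,total,expected",
        [(51, 1355, 3.8), (0, 60, 0.0), (504, 721, 69.9), (315, 406, 77.6)],
    )
    def test_percentage_to_one_decimal(self, errors, total, expected):
        assert error_rate(errors, total) == expected

    def test_zero_denominator_sentinel(self):
        assert error_rate(0, 0) is UNDEFINED
        assert format_error_rate(0, 0).startswith("undefined")

    def test_format(self):
        assert format_error_rate(51, 1355) == "3.8%(51/1355)"


class TestPrevalenceCorrelation:
    def test_proportional_table_is_collinear(self):
        table = [(n, n / 200) for n in (10, 40, 80, 120)]
        assert prevalence_correlation(table).r == pytest.approx(1.0)

    def test_constant_rate_is_undefined(self):
        assert prevalence_correlation([(10, 0.5), (40, 0.5), (80, 0.5)]).r is UNDEFINED

    def test_undefined_rates_excluded(self):
        table = [(10, 0.1), (20, UNDEFINED), (40, 0.4), (80, 0.7), (90, 0.9)]
        res = prevalence_correlation(table)
        assert res.excluded == [1] and res.n_used == 4

    def test_too_few_points_undefined(self):
        assert prevalence_correlation([(1, 0.1), (2, 0.2)]).r is UNDEFINED


class TestCompareMethods:
    def test_identical_paired_samples_null_centered(self):
        x = [0.1, 0.4, 0.3, 0.8, 0.6, 0.2, 0.9]
        res = compare_methods({"a": x, "b": list(x)}, paired=True)
        n = len(x)
        assert res.pairwise[0].statistic == pytest.approx(n * (n + 1) / 4)
        assert res.pairwise[0].p_raw == pytest.approx(1.0)

    def test_bh_matches_sorted_index_formula(self):
        pvals = [0.01, 0.2, 0.03, 0.005, 0.8, 0.04]
        # independent oracle: p_(i) * m / i, cumulative-min from the largest
        m = len(pvals)
        order = np.argsort(pvals)
        adj_sorted = [pvals[j] * m / (i + 1) for i, j in enumerate(order)]
        for i in range(m - 2, -1, -1):
            adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
        brute = [0.0] * m
        for i, j in enumerate(order):
            brute[j] = min(1.0, adj_sorted[i])
        assert benjamini_hochberg(pvals) == pytest.approx(brute)

    def test_bh_monotone_on_ordered_pvalues(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))

    def test_friedman_runs_for_three_methods(self):
        rng = np.random.default_rng(0)
        tables = {m: rng.uniform(size=12).tolist() for m in ("a", "b", "c")}
        res = compare_methods(tables, paired=True)
        assert res.friedman_p is not None
        assert len(res.pairwise) == 3
        stat, p = scipy_stats.friedmanchisquare(*tables.values())
        assert res.friedman_statistic == pytest.approx(stat)

    def test_unpaired_uses_rank_sum(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(1.5, 1, 25)
        res = compare_methods({"a": a, "b": b}, paired=False)
        u, p = scipy_stats.mannwhitneyu(a, b, alternative="two-sided")
        assert res.pairwise[0].p_raw == pytest.approx(p)

    def test_paired_misalignment_rejected(self):
        with pytest.raises(UsageError, match="align"):
            compare_methods({"a": [1, 2, 3], "b": [1, 2]}, paired=True)
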