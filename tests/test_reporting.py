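"""Report rendering, training tuples, and the corruption operator."""

import dataclasses

import numpy as np
import pytest

from cytoreport.errors import ConfigError, ConsistencyError
from cytoreport.extraction import extract_report_statements
from cytoreport.io import read_training_tuples, write_training_tuples
from cytoreport.panel import Degree, Direction, PanelResult, Quantifier, panel_abnormalities
from cytoreport.reporting import (
    CorruptionSpec,
    EditKind,
    SectionLabel,
    apply_corruption_log,
    corrupt_report,
    make_training_tuple,
    render_report,
)
from conftest import make_abnormal


def _statement_units(statements):
    units = set()
    for s in statements:
        quants = ("count", "percent") if s.quantifier == Quantifier.BOTH else (s.quantifier.value,)
        for q in quants:
            if s.abnormal:
                units.add((s.cell_type, q, s.direction.value, s.degree.value))
    return units


def _panel_units(panel, schema):
    units = set()
    for aid, d in panel_abnormalities(panel, schema):
        a = schema.analyte(aid)
        units.add((a.family, a.quantifier.value, d.direction.value, d.degree.value))
    return units


class TestRenderReport:
    def test_normal_panel_states_all_within_reference(self, schema, normal_panel, aliases):
        report = render_report(normal_panel, schema, "harmonized", aliases)
        labels = [s.label for s in report.sections]
        assert SectionLabel.QLP in labels and SectionLabel.BSP in labels
        assert SectionLabel.PBMC not in labels
        assert "within institutional reference ranges" in report.section(SectionLabel.QLP).text
        assert extract_report_statements(report, aliases) == []

    def test_single_abnormality_round_trips(self, schema, normal_panel, aliases):
        panel = make_abnormal(schema, normal_panel, CD4_CT=360.0)  # d=0.10 -> mild
        report = render_report(panel, schema, "harmonized", aliases)
        statements = [s for s in extract_report_statements(report, aliases) if s.abnormal]
        assert [(s.cell_type, s.direction, s.degree, s.quantifier) for s in statements] == [
            ("CD4", Direction.DECREASED, Degree.MILD, Quantifier.COUNT)
        ]

    @pytest.mark.parametrize("style", ["harmonized", "heterogeneous"])
    def test_round_trip_identity_on_random_panels(self, schema, aliases, cohort, style):
        """Extraction over a rendered report recovers the abnormality set."""
        for panel in cohort:
            report = render_report(panel, schema, style, aliases)
            assert _statement_units(extract_report_statements(report, aliases)) == _panel_units(
                panel, schema
            )

    def test_rendering_is_deterministic(self, schema, cohort, aliases):
        for panel in cohort[:10]:
            a = render_report(panel, schema, "heterogeneous", aliases)
            b = render_report(panel, schema, "heterogeneous", aliases)
            assert a.text == b.text

    def test_sentence_spans_tile_text(self, schema, cohort, aliases):
        report = render_report(cohort[0], schema, "heterogeneous", aliases)
        text = report.text
        spans = report.sentence_spans
        assert [text[s:e] for s, e, _ in spans] == [
            sent for _, _, sent in report.iter_sentences()
        ]
        assert all(e1 < s2 for (_, e1, _), (s2, _, _) in zip(spans, spans[1:]))

    def test_unknown_style_rejected(self, schema, normal_panel):
        with pytest.raises(ConfigError, match="unknown report style"):
            render_report(normal_panel, schema, "telegraphic")


class TestTrainingTuple:
    def test_normal_panel_input_all_normal(self, schema, normal_panel, aliases):
        report = render_report(normal_panel, schema, "harmonized", aliases)
        t = make_training_tuple(normal_panel, report, schema)
        phrases = t.input.split("; ")
        assert len(phrases) == 34
        assert all("normal" in p for p in phrases)

    def test_one_abnormality_panel_has_one_nonnormal_phrase(self, schema, normal_panel, aliases):
        panel = make_abnormal(schema, normal_panel, NK_CT=700.0)
        report = render_report(panel, schema, "harmonized", aliases)
        phrases = make_training_tuple(panel, report, schema).input.split("; ")
        assert sum("normal" not in p for p in phrases) == 1

    def test_specimen_mismatch_rejected(self, schema, normal_panel, cohort, aliases):
        report = render_report(cohort[0], schema, "harmonized", aliases)
        with pytest.raises(ConsistencyError):
            make_training_tuple(normal_panel, report, schema)

    def test_jsonl_round_trip(self, schema, cohort, aliases, tmp_path):
        tuples = [
            make_training_tuple(p, render_report(p, schema, "harmonized", aliases), schema)
            for p in cohort[:5]
        ]
        path = tmp_path / "tuples.jsonl"
        write_training_tuples(path, tuples)
        assert read_training_tuples(path) == tuples


class TestCorruptReport:
    def test_zero_rates_are_identity(self, schema, cohort, aliases):
        panel = cohort[0]
        report = render_report(panel, schema, "harmonized", aliases)
        corrupted, log = corrupt_report(report, panel, schema, CorruptionSpec(), seed=3)
        assert log == []
        assert corrupted.comments == report.comments
        assert _statement_units(
            extract_report_statements(corrupted, aliases)
        ) == _panel_units(panel, schema)

    def test_full_omission_removes_every_comment(self, schema, cohort, aliases):
        panel = next(p for p in cohort if panel_abnormalities(p, schema))
        report = render_report(panel, schema, "harmonized", aliases)
        corrupted, log = corrupt_report(
            report, panel, schema, CorruptionSpec(omit_comment=1.0), seed=3
        )
        assert corrupted.comments == []
        assert len(log) == len(report.comments)
        assert all(e.kind == EditKind.OMIT_COMMENT for e in log)
        assert [s for s in extract_report_statements(corrupted, aliases) if s.abnormal] == []

    def test_flip_rate_binomial(self, schema, cohort, aliases):
        """Across the cohort, a 0.5 flip rate flips about half the comments."""
        total = flipped = 0
        for i, panel in enumerate(cohort):
            report = render_report(panel, schema, "harmonized", aliases)
            _, log = corrupt_report(
                report, panel, schema, CorruptionSpec(flip_direction=0.5), seed=100 + i
            )
            total += len(report.comments)
            flipped += sum(e.kind == EditKind.FLIP_DIRECTION for e in log)
        se = np.sqrt(0.25 * total)
        assert abs(flipped - 0.5 * total) < 3 * se

    def test_log_replay_matches_corrupted_comments(self, schema, cohort, aliases):
        spec = CorruptionSpec(
            omit_comment=0.3,
            flip_direction=0.3,
            shift_degree=0.3,
            swap_quantifier=0.3,
            hallucinate_statement=0.3,
        )
        for i, panel in enumerate(cohort[:20]):
            report = render_report(panel, schema, "heterogeneous", aliases)
            corrupted, log = corrupt_report(
                report, panel, schema, spec, seed=i, style="heterogeneous", aliases=aliases
            )
            assert apply_corruption_log(report.comments, log) == corrupted.comments

    def test_same_seed_same_edits(self, schema, cohort, aliases):
        panel = next(p for p in cohort if len(panel_abnormalities(p, schema)) > 2)
        report = render_report(panel, schema, "harmonized", aliases)
        spec = CorruptionSpec(omit_comment=0.5, flip_direction=0.5)
        _, log1 = corrupt_report(report, panel, schema, spec, seed=9)
        _, log2 = corrupt_report(report, panel, schema, spec, seed=9)
        assert log1 == log2

    def test_hallucinations_target_in_range_analytes(self, schema, cohort, aliases):
        for i, panel in enumerate(cohort[:20]):
            report = render_report(panel, schema, "harmonized", aliases)
            _, log = corrupt_report(
                report, panel, schema, CorruptionSpec(hallucinate_statement=1.0), seed=i
            )
            abnormal_families = {
                (schema.analyte(aid).family, schema.analyte(aid).quantifier)
                for aid, _ in panel_abnormalities(panel, schema)
            }
            for edit in log:
                if edit.kind == EditKind.HALLUCINATE_STATEMENT:
                    assert (edit.after.family, edit.after.quantifier) not in abnormal_families
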