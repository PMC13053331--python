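"""Schema validation and the numeric -> qualitative descriptor transform."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytoreport.errors import DomainError, SchemaError
from cytoreport.panel import (
    Degree,
    DegreeThresholds,
    Direction,
    Group,
    PanelResult,
    Quantifier,
    ReferenceRange,
    classify_value,
    panel_abnormalities,
    parse_schema,
    validate_panel,
)

THRESH = DegreeThresholds(mild=0.25, significant=0.5)


def _minimal_schema(analytes):
    return {"name": "t", "analytes": analytes}


def _analyte(aid, lower=100, upper=200, **kw):
    base = {
        "analyte_id": aid,
        "display_name": aid,
        "family": kw.pop("family", aid),
        "group": "QLP",
        "quantifier": kw.pop("quantifier", "count"),
        "units": "cells/mcL",
        "reference_ranges": [{"lower": lower, "upper": upper}],
    }
    base.update(kw)
    return base


class TestSchema:
    def test_bundled_schema_has_34_analytes(self, schema):
        assert len(schema.analytes) == 34
        assert len(schema.by_group(Group.QLP)) == 12
        assert len(schema.by_group(Group.BSP)) == 22
        # six QLP populations, eleven BSP subsets, each count + percent
        assert len(schema.families(Group.QLP)) == 6
        assert len(schema.families(Group.BSP)) == 11

    def test_duplicate_analyte_id_rejected(self):
        with pytest.raises(SchemaError, match="duplicate"):
            parse_schema(_minimal_schema([_analyte("A"), _analyte("A")]))

    def test_inverted_range_rejected(self):
        with pytest.raises(SchemaError):
            parse_schema(_minimal_schema([_analyte("A", lower=200, upper=100)]))

    def test_overlapping_age_bands_rejected(self):
        a = _analyte("A")
        a["reference_ranges"] = [
            {"lower": 1, "upper": 2, "age_band": [0, 18]},
            {"lower": 1, "upper": 3, "age_band": [10, 60]},
        ]
        with pytest.raises(SchemaError, match="overlap"):
            parse_schema(_minimal_schema([a]))

    def test_pairing_must_be_opposite_quantifier(self):
        a = _analyte("A_CT", paired_analyte_id="A2_CT", family="A")
        b = _analyte("A2_CT", paired_analyte_id="A_CT", family="A")
        with pytest.raises(SchemaError, match="opposite quantifier"):
            parse_schema(_minimal_schema([a, b]))

    def test_panel_missing_analyte_needs_flag(self, schema, normal_panel):
        values = dict(normal_panel.values)
        values.pop("CD4_CT")
        broken = PanelResult("X", 37.0, values)
        with pytest.raises(SchemaError, match="absent without flag"):
            validate_panel(broken, schema)
        values["CD4_CT"] = None  # explicit missing flag is allowed
        validate_panel(PanelResult("X", 37.0, values), schema)


class TestClassifyValue:
    RANGE = ReferenceRange(lower=100, upper=200)

    @pytest.mark.parametrize("value", [100.0, 150.0, 200.0])
    def test_in_range_and_boundaries_are_normal(self, value):
        d = classify_value(value, self.RANGE, THRESH)
        assert d.direction == Direction.NORMAL and d.degree == Degree.NONE

    @pytest.mark.parametrize(
        "value,direction,degree",
        [
            # d = (100-90)/100 = 0.10 -> mild
            (90, Direction.DECREASED, Degree.MILD),
            # d = (100-70)/100 = 0.30 -> moderate
            (70, Direction.DECREASED, Degree.MODERATE),
            # d = (100-40)/100 = 0.60 -> significant
            (40, Direction.DECREASED, Degree.SIGNIFICANT),
            # d = (230-200)/200 = 0.15 -> mild
            (230, Direction.INCREASED, Degree.MILD),
            # d = (450-200)/200 = 1.25 -> significant
            (450, Direction.INCREASED, Degree.SIGNIFICANT),
        ],
    )
    def test_excursion_degrees(self, value, direction, degree):
        d = classify_value(value, self.RANGE, THRESH)
        assert (d.direction, d.degree) == (direction, degree)

    def test_negative_value_rejected(self):
        with pytest.raises(DomainError):
            classify_value(-1.0, self.RANGE, THRESH)

    def test_zero_lower_range_cannot_be_undershot(self):
        rng = ReferenceRange(lower=0, upper=10)
        assert classify_value(0.0, rng, THRESH).direction == Direction.NORMAL
        assert classify_value(16.0, rng, THRESH).degree == Degree.SIGNIFICANT

    @given(
        v1=st.floats(min_value=0, max_value=99.999),
        v2=st.floats(min_value=0, max_value=99.999),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_below_range(self, v1, v2):
        """Moving further below the range never lowers the degree."""
        lo, hi = sorted([v1, v2])
        order = {Degree.MILD: 1, Degree.MODERATE: 2, Degree.SIGNIFICANT: 3}
        d_far = classify_value(lo, self.RANGE, THRESH)
        d_near = classify_value(hi, self.RANGE, THRESH)
        assert order[d_far.degree] >= order[d_near.degree]

    @given(v=st.floats(min_value=0, max_value=1000))
    @settings(max_examples=200, deadline=None)
    def test_normal_iff_inside_range(self, v):
        d = classify_value(v, self.RANGE, THRESH)
        assert (d.direction == Direction.NORMAL) == (100 <= v <= 200)


class TestPanelAbnormalities:
    def test_fully_normal_panel_is_empty(self, schema, normal_panel):
        assert panel_abnormalities(normal_panel, schema) == []

    def test_counts_six_forced_abnormalities(self, schema, normal_panel):
        values = dict(normal_panel.values)
        for aid in ["CD3_CT", "CD4_CT", "CD8_PCT", "NK_CT", "NAIVE_PCT", "CD21LOW_CT"]:
            r = schema.range_for(aid, 37.0)
            values[aid] = r.upper * 1.3
        panel = PanelResult("SIX", 37.0, values)
        assert len(panel_abnormalities(panel, schema)) == 6

    def test_matches_brute_force_range_check(self, schema, cohort):
        """Abnormality listing equals a direct per-value range comparison."""
        for panel in cohort:
            brute = [
                a.analyte_id
                for a in schema.analytes
                if panel.values[a.analyte_id] is not None
                and not (
                    schema.range_for(a.analyte_id, panel.patient_age).lower
                    <= panel.values[a.analyte_id]
                    <= schema.range_for(a.analyte_id, panel.patient_age).upper
                )
            ]
            assert [aid for aid, _ in panel_abnormalities(panel, schema)] == brute

    def test_unknown_analyte_rejected(self, schema, normal_panel):
        values = dict(normal_panel.values)
        values["HEMOGLOBIN"] = 14.0
        with pytest.raises(SchemaError, match="not in schema"):
            panel_abnormalities(PanelResult("X", 37.0, values), schema)
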