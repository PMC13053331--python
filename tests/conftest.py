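import numpy as np
import pytest

from cytoreport.extraction import default_aliases
from cytoreport.interpretation import default_checklist
from cytoreport.panel import PanelResult, default_schema
from cytoreport.synthetic import table1_profile, generate_cohort


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def aliases():
    return default_aliases()


@pytest.fixture(scope="session")
def checklist():
    return default_checklist()


@pytest.fixture(scope="session")
def cohort(schema):
    """A small, seed-fixed cohort shared by read-only tests."""
    return generate_cohort(table1_profile(n=60, seed=11), schema)


@pytest.fixture()
def normal_panel(schema):
    """A panel with every value at its range midpoint (fully normal)."""
    values = {}
    for a in schema.analytes:
        r = schema.range_for(a.analyte_id, 37.0)
        values[a.analyte_id] = (r.lower + r.upper) / 2
    return PanelResult(specimen_id="NORM-1", patient_age=37.0, values=values)


def make_abnormal(schema, base_panel, **overrides):
    """Copy a normal panel, overriding selected analyte values."""
    values = dict(base_panel.values)
    values.update(overrides)
    return PanelResult(
        specimen_id=base_panel.specimen_id,
        patient_age=base_panel.patient_age,
        values=values,
    )
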