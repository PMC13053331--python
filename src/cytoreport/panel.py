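"""Panel schema, reference ranges, and qualitative descriptors.

A combined QLP/BSP panel carries 34 reportable results: absolute counts
(cells/mcL) and relative percentages for six whole-blood lymphocyte
populations (quantitative lymphocyte profiling, QLP) and eleven PBMC-based
B-cell subsets (B-cell subset phenotyping, BSP).  Each numeric result is
mapped against an institutional reference range into a qualitative
descriptor: a direction (decreased / normal / increased) and, when outside
the range, a degree (mild / moderate / significant) derived from the
relative excursion beyond the nearer range limit.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import DomainError, SchemaError

try:  # Python >= 3.9
    from importlib import resources as _resources
except ImportError:  # pragma: no cover
    import importlib_resources as _resources  # type: ignore


class Group(str, enum.Enum):
    QLP = "QLP"
    BSP = "BSP"


class Quantifier(str, enum.Enum):
    COUNT = "count"
    PERCENT = "percent"
    # The two values below never label an analyte; they only occur in
    # narrative statements ("counts and percentages", or no quantifier cue).
    BOTH = "both"
    UNSPECIFIED = "unspecified"


class Direction(str, enum.Enum):
    DECREASED = "decreased"
    NORMAL = "normal"
    INCREASED = "increased"


class Degree(str, enum.Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SIGNIFICANT = "significant"
    # Extraction-only: a direction cue without a magnitude adverb.
    UNSPECIFIED = "unspecified"


ABNORMAL_DEGREES = (Degree.MILD, Degree.MODERATE, Degree.SIGNIFICANT)


@dataclass(frozen=True)
class Descriptor:
    """Qualitative label for one analyte value.

    Invariant: ``direction == NORMAL`` exactly when ``degree == NONE``.
    """

    direction: Direction
    degree: Degree
    quantifier: Quantifier = Quantifier.COUNT

    def __post_init__(self) -> None:
        normal = self.direction == Direction.NORMAL
        if normal != (self.degree == Degree.NONE):
            raise DomainError(
                f"inconsistent descriptor: direction={self.direction.value}, "
                f"degree={self.degree.value}"
            )

    @property
    def abnormal(self) -> bool:
        return self.direction != Direction.NORMAL

    def phrase(self) -> str:
        """Human-readable rendering, e.g. ``mildly decreased``."""
        if not self.abnormal:
            return "normal"
        adverb = {
            Degree.MILD: "mildly",
            Degree.MODERATE: "moderately",
            Degree.SIGNIFICANT: "significantly",
            Degree.UNSPECIFIED: "",
        }[self.degree]
        return f"{adverb} {self.direction.value}".strip()


class ReferenceRange(BaseModel):
    """Institutional reference interval, optionally restricted to an age band."""

    lower: float = Field(ge=0)
    upper: float
    age_band: Optional[tuple[float, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "ReferenceRange":
        if not self.upper > self.lower:
            raise ValueError(f"upper ({self.upper}) must exceed lower ({self.lower})")
        if self.age_band is not None:
            lo, hi = self.age_band
            if lo < 0 or hi <= lo:
                raise ValueError(f"invalid age band {self.age_band}")
        return self

    def contains_age(self, age: float) -> bool:
        if self.age_band is None:
            return True
        lo, hi = self.age_band
        return lo <= age < hi


class DegreeThresholds(BaseModel):
    """Relative-excursion cutpoints separating mild / moderate / significant.

    For a value below the range the excursion is d = (lower - value) / lower;
    above it is d = (value - upper) / upper.  Degree is mild for d < mild,
    moderate for mild <= d < significant, significant otherwise.
    """

    mild: float = Field(default=0.25, gt=0)
    significant: float = Field(default=0.5)

    @model_validator(mode="after")
    def _check(self) -> "DegreeThresholds":
        if not self.mild < self.significant:
            raise ValueError("mild threshold must be below significant threshold")
        return self


class AnalyteDef(BaseModel):
    analyte_id: str
    display_name: str
    family: str
    group: Group
    quantifier: Quantifier
    units: str
    paired_analyte_id: Optional[str] = None
    reference_ranges: list[ReferenceRange] = Field(min_length=1)

    @model_validator(mode="after")
    def _check(self) -> "AnalyteDef":
        if self.quantifier not in (Quantifier.COUNT, Quantifier.PERCENT):
            raise ValueError(
                f"analyte quantifier must be count or percent, got {self.quantifier}"
            )
        banded = [r for r in self.reference_ranges if r.age_band is not None]
        if len(self.reference_ranges) > 1 and len(banded) != len(self.reference_ranges):
            raise ValueError(
                f"{self.analyte_id}: multiple reference ranges require age bands on all"
            )
        bands = sorted((r.age_band for r in banded), key=lambda b: b[0])
        for (a_lo, a_hi), (b_lo, b_hi) in zip(bands, bands[1:]):
            if b_lo < a_hi:
                raise ValueError(f"{self.analyte_id}: overlapping age bands")
        return self


class PanelSchema(BaseModel):
    """Validated set of analytes with ranges and degree cutpoints."""

    name: str
    thresholds: DegreeThresholds = DegreeThresholds()
    analytes: list[AnalyteDef]

    @model_validator(mode="after")
    def _check(self) -> "PanelSchema":
        ids = [a.analyte_id for a in self.analytes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate analyte_id: {dupes}")
        by_id = {a.analyte_id: a for a in self.analytes}
        for a in self.analytes:
            if a.paired_analyte_id is None:
                continue
            twin = by_id.get(a.paired_analyte_id)
            if twin is None:
                raise ValueError(f"{a.analyte_id}: unknown paired analyte {a.paired_analyte_id}")
            if twin.quantifier == a.quantifier:
                raise ValueError(f"{a.analyte_id}: paired analyte must have opposite quantifier")
            if twin.family != a.family:
                raise ValueError(f"{a.analyte_id}: paired analyte must share the cell family")
        return self

    # -- lookups -------------------------------------------------------

    @property
    def analyte_ids(self) -> list[str]:
        return [a.analyte_id for a in self.analytes]

    def analyte(self, analyte_id: str) -> AnalyteDef:
        for a in self.analytes:
            if a.analyte_id == analyte_id:
                return a
        raise SchemaError(f"unknown analyte: {analyte_id}")

    def families(self, group: Optional[Group] = None) -> list[str]:
        seen: list[str] = []
        for a in self.analytes:
            if group is not None and a.group != group:
                continue
            if a.family not in seen:
                seen.append(a.family)
        return seen

    def family_analytes(self, family: str) -> list[AnalyteDef]:
        out = [a for a in self.analytes if a.family == family]
        if not out:
            raise SchemaError(f"unknown cell family: {family}")
        return out

    def by_group(self, group: Group) -> list[AnalyteDef]:
        return [a for a in self.analytes if a.group == group]

    def range_for(self, analyte_id: str, age: Optional[float] = None) -> ReferenceRange:
        a = self.analyte(analyte_id)
        if len(a.reference_ranges) == 1 and a.reference_ranges[0].age_band is None:
            return a.reference_ranges[0]
        if age is None:
            raise SchemaError(f"{analyte_id}: age required for age-banded ranges")
        for r in a.reference_ranges:
            if r.contains_age(age):
                return r
        raise SchemaError(f"{analyte_id}: no reference range covers age {age}")


@dataclass
class PanelResult:
    """One specimen's panel values.

    Every schema analyte must appear as a key.  A value of ``None`` is an
    explicit missing flag; missing analytes are excluded from all downstream
    denominators.
    """

    specimen_id: str
    patient_age: float
    values: dict[str, Optional[float]] = field(default_factory=dict)


def validate_panel(panel: PanelResult, schema: PanelSchema) -> None:
    """Raise SchemaError/DomainError if the panel does not conform to the schema."""
    if panel.patient_age < 0:
        raise DomainError(f"{panel.specimen_id}: negative patient age")
    want = set(schema.analyte_ids)
    have = set(panel.values)
    missing = sorted(want - have)
    extra = sorted(have - want)
    if missing:
        raise SchemaError(f"{panel.specimen_id}: analytes absent without flag: {missing}")
    if extra:
        raise SchemaError(f"{panel.specimen_id}: analytes not in schema: {extra}")
    for aid, v in panel.values.items():
        if v is not None and v < 0:
            raise DomainError(f"{panel.specimen_id}: negative value for {aid}: {v}")


def classify_value(
    value: float,
    rng: ReferenceRange,
    thresholds: DegreeThresholds,
    quantifier: Quantifier = Quantifier.COUNT,
) -> Descriptor:
    """Map a numeric result to its qualitative descriptor.

    Boundary values (value == lower or value == upper) are normal: an
    abnormality is a value strictly outside the reference interval.  The
    degree comes from the relative excursion beyond the nearer limit; a
    range with lower == 0 cannot be undershot by a non-negative value, so
    the decreased branch never divides by zero.
    """
    if value < 0:
        raise DomainError(f"negative value: {value}")
    if rng.lower <= value <= rng.upper:
        return Descriptor(Direction.NORMAL, Degree.NONE, quantifier)
    if value < rng.lower:
        direction = Direction.DECREASED
        excursion = (rng.lower - value) / rng.lower
    else:
        direction = Direction.INCREASED
        excursion = (value - rng.upper) / rng.upper
    if excursion < thresholds.mild:
        degree = Degree.MILD
    elif excursion < thresholds.significant:
        degree = Degree.MODERATE
    else:
        degree = Degree.SIGNIFICANT
    return Descriptor(direction, degree, quantifier)


def classify_analyte(panel: PanelResult, schema: PanelSchema, analyte_id: str) -> Optional[Descriptor]:
    """Descriptor for one analyte of a panel, or None when the value is missing."""
    value = panel.values[analyte_id]
    if value is None:
        return None
    a = schema.analyte(analyte_id)
    r = schema.range_for(analyte_id, panel.patient_age)
    return classify_value(value, r, schema.thresholds, a.quantifier)


def panel_abnormalities(
    panel: PanelResult, schema: PanelSchema
) -> list[tuple[str, Descriptor]]:
    """All out-of-range analytes of a panel, in schema order."""
    validate_panel(panel, schema)
    out: list[tuple[str, Descriptor]] = []
    for a in schema.analytes:
        d = classify_analyte(panel, schema, a.analyte_id)
        if d is not None and d.abnormal:
            out.append((a.analyte_id, d))
    return out


# -- schema I/O -------------------------------------------------------------


def load_schema(path: str | Path) -> PanelSchema:
    """Load and validate a schema from a JSON or YAML config file."""
    path = Path(path)
    try:
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    except (OSError, ValueError, yaml.YAMLError) as exc:
        raise SchemaError(f"cannot parse schema file {path}: {exc}") from exc
    return parse_schema(raw)


def parse_schema(raw: dict) -> PanelSchema:
    try:
        return PanelSchema.model_validate(raw)
    except ValidationError as exc:
        raise SchemaError(f"invalid schema: {exc}") from exc


def default_schema() -> PanelSchema:
    """The bundled 34-analyte QLP/BSP schema.

    Six QLP populations and eleven BSP subsets, each reported as an absolute
    count and a percentage.  The numeric limits are plausible adult values;
    institutional ranges are site-specific and should be supplied via
    ``load_schema`` in production use.
    """
    data = _resources.files("cytoreport.data").joinpath("schema.json").read_text()
    return parse_schema(json.loads(data))
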