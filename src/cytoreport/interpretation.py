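"""Clinical-interpretation scoring against a binary attribute checklist.

Interpretation sections are compared not by textual overlap but by a fixed
checklist of clinically relevant yes/no attributes (does the text describe
a B-cell abnormality, raise a diagnostic consideration, recommend further
evaluation, ...).  The same detectors are applied uniformly to generated
and reference texts — one code path, no per-source branching — and
agreement is summarized per attribute as accuracy, sensitivity, and
specificity over a corpus of report pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import ConfigError, SchemaError, UsageError
from .extraction import normalize_text
from .panel import (
    Degree,
    Direction,
    Group,
    PanelResult,
    PanelSchema,
    Quantifier,
    classify_analyte,
    panel_abnormalities,
)

_NEG_TOKENS = re.compile(r"\b(?:no|not|without|absent|neither)\b")
_CLAUSE_SPLIT = re.compile(r"[.;:,]")


class AttributeDef(BaseModel):
    attribute_id: str
    question: str
    patterns: list[str] = Field(min_length=1)
    marker: str
    rule: str = "never"


class AttributeChecklist(BaseModel):
    attributes: list[AttributeDef]

    @model_validator(mode="after")
    def _check(self) -> "AttributeChecklist":
        ids = [a.attribute_id for a in self.attributes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate attribute_id in checklist")
        return self

    @property
    def ids(self) -> list[str]:
        return [a.attribute_id for a in self.attributes]

    def get(self, attribute_id: str) -> AttributeDef:
        for a in self.attributes:
            if a.attribute_id == attribute_id:
                return a
        raise ConfigError(f"unknown attribute: {attribute_id}")


#: present/absent judgment for every checklist attribute
AttributeVector = dict[str, bool]


def load_checklist(path: str | Path) -> AttributeChecklist:
    try:
        raw = yaml.safe_load(Path(path).read_text())
        return AttributeChecklist.model_validate(raw)
    except (OSError, yaml.YAMLError, ValidationError) as exc:
        raise ConfigError(f"cannot load checklist {path}: {exc}") from exc


def default_checklist() -> AttributeChecklist:
    """The bundled 18-attribute checklist."""
    from importlib import resources

    raw = yaml.safe_load(
        resources.files("cytoreport.data").joinpath("checklist.yaml").read_text()
    )
    return AttributeChecklist.model_validate(raw)


def _clause_negated(clause: str, cue_start: int) -> bool:
    """True when a negation token precedes the cue within its clause."""
    return bool(_NEG_TOKENS.search(clause[:cue_start]))


def attribute_vector(interpretation_text: str, checklist: AttributeChecklist) -> AttributeVector:
    """Evaluate every checklist attribute against an interpretation text.

    Detection is per clause (split on sentence-internal punctuation): an
    attribute is present when any clause matches one of its patterns
    outside a negation scope.  Empty text yields an all-false vector.
    """
    vector: AttributeVector = {a.attribute_id: False for a in checklist.attributes}
    text = normalize_text(interpretation_text or "")
    if not text:
        return vector
    clauses = [c for c in _CLAUSE_SPLIT.split(text) if c.strip()]
    for attr in checklist.attributes:
        for pattern in attr.patterns:
            pat = re.compile(pattern)
            hit = False
            for clause in clauses:
                m = pat.search(clause)
                if m and not _clause_negated(clause, m.start()):
                    hit = True
                    break
            if hit:
                vector[attr.attribute_id] = True
                break
    return vector


# -- panel -> attribute rules (used by the reference report renderer) -------


def _eval_primitive(token: str, ctx: "_RuleContext") -> bool:
    if token == "any_abnormal":
        return ctx.any_abnormal
    if token == "no_abnormal":
        return not ctx.any_abnormal
    if token == "pbmc_expected":
        return ctx.pbmc
    if token == "never":
        return False
    if token.startswith("any_abnormal_group:"):
        return token.split(":", 1)[1] in ctx.abnormal_groups
    if token.startswith("abnormal_family:"):
        return token.split(":", 1)[1] in ctx.abnormal_families
    if token.startswith(("decreased:", "increased:")):
        direction, family, quant = token.split(":")
        want = Direction(direction)
        for q, d in ctx.family_descriptors.get(family, []):
            if d.direction == want and (quant == "any" or q.value == quant):
                return True
        return False
    raise ConfigError(f"unknown rule primitive: {token}")


@dataclass
class _RuleContext:
    any_abnormal: bool
    abnormal_groups: set[str]
    abnormal_families: set[str]
    family_descriptors: dict[str, list[tuple[Quantifier, object]]]
    pbmc: bool


def panel_attributes(
    panel: PanelResult,
    schema: PanelSchema,
    checklist: AttributeChecklist,
    pbmc_expected: bool,
) -> AttributeVector:
    """Ground-truth attribute vector implied by a panel's laboratory values."""
    abn = panel_abnormalities(panel, schema)
    fam_desc: dict[str, list[tuple[Quantifier, object]]] = {}
    groups: set[str] = set()
    for aid, desc in abn:
        a = schema.analyte(aid)
        fam_desc.setdefault(a.family, []).append((a.quantifier, desc))
        groups.add(a.group.value)
    ctx = _RuleContext(
        any_abnormal=bool(abn),
        abnormal_groups=groups,
        abnormal_families=set(fam_desc),
        family_descriptors=fam_desc,
        pbmc=pbmc_expected,
    )
    vector: AttributeVector = {}
    for attr in checklist.attributes:
        value = False
        for disjunct in attr.rule.split("|"):
            conj = [t.strip() for t in disjunct.split("&") if t.strip()]
            if conj and all(_eval_primitive(t, ctx) for t in conj):
                value = True
                break
        vector[attr.attribute_id] = value
    return vector


def render_interpretation(vector: AttributeVector, checklist: AttributeChecklist) -> list[str]:
    """Marker sentences for every active attribute, in checklist order."""
    return [a.marker for a in checklist.attributes if vector.get(a.attribute_id)]


# -- agreement metrics ------------------------------------------------------


@dataclass
class ConfusionTally:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def add(self, generated: bool, reference: bool) -> None:
        if generated and reference:
            self.tp += 1
        elif generated and not reference:
            self.fp += 1
        elif not generated and reference:
            self.fn += 1
        else:
            self.tn += 1

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> Optional[float]:
        return (self.tp + self.tn) / self.total if self.total else None

    @property
    def sensitivity(self) -> Optional[float]:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> Optional[float]:
        neg = self.fp + self.tn
        return self.tn / neg if neg else None


def compare_attributes(
    generated: AttributeVector, reference: AttributeVector
) -> dict[str, ConfusionTally]:
    """Per-attribute 2x2 cell for one generated/reference pair."""
    if set(generated) != set(reference):
        raise UsageError("attribute vectors come from different checklists")
    out: dict[str, ConfusionTally] = {}
    for attr_id in generated:
        tally = ConfusionTally()
        tally.add(generated[attr_id], reference[attr_id])
        out[attr_id] = tally
    return out


def aggregate_attributes(
    pairs: Iterable[tuple[AttributeVector, AttributeVector]]
) -> dict[str, ConfusionTally]:
    """Pooled per-attribute confusion tallies over a corpus of report pairs."""
    pooled: dict[str, ConfusionTally] = {}
    for generated, reference in pairs:
        for attr_id, tally in compare_attributes(generated, reference).items():
            pooled.setdefault(attr_id, ConfusionTally())
            t = pooled[attr_id]
            t.tp += tally.tp
            t.fp += tally.fp
            t.fn += tally.fn
            t.tn += tally.tn
    return pooled
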