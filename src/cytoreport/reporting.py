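"""Deterministic narrative report rendering, training tuples, and corruption.

The renderer is the package's reference author ("pathologist oracle"): it
turns a panel into a four-section narrative (QLP, PBMC, BSP, clinical
interpretation) whose abnormality comments name the cell type, direction,
degree, and quantifier in the canonical vocabulary.  Because rendering is
an exact inverse of statement extraction, every evaluation metric can be
verified by round-trip identity, and the corruption operator can plant
known omissions, direction flips, degree shifts, quantifier swaps, and
hallucinated statements whose metric consequences are fully predictable
from the edit log.
"""

from __future__ import annotations

import copy
import enum
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Optional

import numpy as np
from pydantic import BaseModel, Field

from .errors import ConfigError, ConsistencyError
from .extraction import AliasDictionary, ExtractedStatement, default_aliases
from .interpretation import (
    AttributeChecklist,
    default_checklist,
    panel_attributes,
    render_interpretation,
)
from .panel import (
    Degree,
    Descriptor,
    Direction,
    Group,
    PanelResult,
    PanelSchema,
    Quantifier,
    classify_analyte,
    panel_abnormalities,
)


class SectionLabel(str, enum.Enum):
    QLP = "QLP"
    PBMC = "PBMC"
    BSP = "BSP"
    INTERP = "INTERP"


SECTION_ORDER = [SectionLabel.QLP, SectionLabel.PBMC, SectionLabel.BSP, SectionLabel.INTERP]


@dataclass
class ReportSection:
    label: SectionLabel
    sentences: list[str]

    @property
    def text(self) -> str:
        return " ".join(self.sentences)


@dataclass(frozen=True)
class RenderedComment:
    """One abnormality comment as authored: the renderer's ground truth."""

    family: str
    group: Group
    quantifier: Quantifier  # count, percent, or both
    direction: Direction
    degree: Degree

    def to_statement(self, sentence_index: int = -1) -> ExtractedStatement:
        return ExtractedStatement(
            cell_type=self.family,
            direction=self.direction,
            degree=self.degree,
            quantifier=self.quantifier,
            source_sentence_index=sentence_index,
        )


@dataclass
class Report:
    """Four-section narrative report with per-sentence section labels."""

    specimen_id: str
    sections: list[ReportSection]
    comments: list[RenderedComment] = field(default_factory=list)
    attributes: Optional[dict[str, bool]] = None

    @property
    def text(self) -> str:
        return " ".join(s.text for s in self.sections if s.sentences)

    def section(self, label: SectionLabel) -> Optional[ReportSection]:
        for s in self.sections:
            if s.label == label:
                return s
        return None

    def iter_sentences(self) -> Iterator[tuple[int, SectionLabel, str]]:
        idx = 0
        for s in self.sections:
            for sentence in s.sentences:
                yield idx, s.label, sentence
                idx += 1

    @property
    def sentence_spans(self) -> list[tuple[int, int, SectionLabel]]:
        """(start, end, label) spans over the concatenated report text."""
        spans = []
        offset = 0
        for _, label, sentence in self.iter_sentences():
            start = offset
            end = start + len(sentence)
            spans.append((start, end, label))
            offset = end + 1  # single-space joiner
        return spans

    @property
    def n_sentences(self) -> int:
        return sum(len(s.sentences) for s in self.sections)


class ReportStyle(BaseModel):
    """Surface-realization parameters for the deterministic renderer.

    ``harmonized`` mirrors a two-author, uniform reporting style: one
    preferred surface form per cell type, a single sentence frame, twins
    always merged into compound comments.  ``heterogeneous`` emulates a
    multi-author corpus: synonym slots, alternating sentence frames,
    probabilistic compound merging, clause merging, and shuffled comment
    order.
    """

    style_id: str
    synonym_pool: int = Field(default=1, ge=1)
    template_pool: int = Field(default=1, ge=1, le=2)
    compound_prob: float = Field(default=1.0, ge=0, le=1)
    clause_merge_prob: float = Field(default=0.0, ge=0, le=1)
    shuffle: bool = False
    seed_salt: int = 0


STYLES: dict[str, ReportStyle] = {
    "harmonized": ReportStyle(style_id="harmonized"),
    "heterogeneous": ReportStyle(
        style_id="heterogeneous",
        synonym_pool=3,
        template_pool=2,
        compound_prob=0.5,
        clause_merge_prob=0.35,
        shuffle=True,
        seed_salt=17,
    ),
}


def get_style(style: str | ReportStyle) -> ReportStyle:
    if isinstance(style, ReportStyle):
        return style
    try:
        return STYLES[style]
    except KeyError:
        raise ConfigError(f"unknown report style: {style!r}") from None


_DEGREE_ADVERBS = {
    Degree.MILD: ["mildly", "slightly"],
    Degree.MODERATE: ["moderately"],
    Degree.SIGNIFICANT: ["significantly", "markedly"],
}
_DIRECTION_WORDS = {
    Direction.DECREASED: ["decreased", "reduced"],
    Direction.INCREASED: ["increased", "elevated"],
}
_QTY_PHRASE = {
    Quantifier.COUNT: "absolute count",
    Quantifier.PERCENT: "percentage",
    Quantifier.BOTH: "absolute count and percentage",
}

QLP_NORMAL_SENTENCE = (
    "Quantitative lymphocyte profiling demonstrates T-, B-, and NK-cell "
    "populations within institutional reference ranges."
)
BSP_NORMAL_SENTENCE = (
    "B-cell subset phenotyping demonstrates subset distributions within "
    "institutional reference ranges."
)
PBMC_SENTENCE = (
    "PBMC analysis demonstrates reduced B-cell recovery; absolute subset "
    "values may be artifactually lowered."
)

DEFAULT_INSTRUCTION = (
    "Write the interpretive report for the following quantitative lymphocyte "
    "profiling and B-cell subset phenotyping results."
)


def _render_seed(specimen_id: str, style: ReportStyle, extra: int = 0) -> int:
    h = zlib.crc32(f"{style.style_id}:{specimen_id}".encode())
    return int((h + style.seed_salt + extra) % (2**31))


def _comment_clause(
    comment: RenderedComment,
    surface: str,
    template: int,
    rng: np.random.Generator,
    style: ReportStyle,
) -> str:
    adverbs = _DEGREE_ADVERBS[comment.degree]
    directions = _DIRECTION_WORDS[comment.direction]
    pick = lambda pool: pool[int(rng.integers(len(pool)))] if style.synonym_pool > 1 else pool[0]
    adv, dirword = pick(adverbs), pick(directions)
    qty = _QTY_PHRASE[comment.quantifier]
    verb = "are" if comment.quantifier == Quantifier.BOTH else "is"
    if template == 1:
        return f"the {qty} of {surface} {verb} {adv} {dirword}"
    return f"{surface} {qty} {verb} {adv} {dirword}"


def _capitalize(clause: str) -> str:
    return clause[0].upper() + clause[1:] if clause else clause


def _realize_comment_section(
    comments: list[RenderedComment],
    normal_sentence: str,
    aliases: AliasDictionary,
    style: ReportStyle,
    rng: np.random.Generator,
) -> list[str]:
    if not comments:
        return [normal_sentence]
    order = list(comments)
    if style.shuffle and len(order) > 1:
        perm = rng.permutation(len(order))
        order = [order[int(i)] for i in perm]
    # Decide clause merges first: merged clauses always use the
    # subject-first frame so each mention's cue scope stays local.
    sentences: list[str] = []
    i = 0
    while i < len(order):
        merge = (
            i + 1 < len(order)
            and style.clause_merge_prob > 0
            and rng.random() < style.clause_merge_prob
        )
        group_comments = order[i : i + 2] if merge else order[i : i + 1]
        clauses = []
        for j, c in enumerate(group_comments):
            pool = aliases.surface_pool(c.family, style.synonym_pool)
            surface = pool[int(rng.integers(len(pool)))] if len(pool) > 1 else pool[0]
            if merge:
                template = 0
            else:
                template = int(rng.integers(style.template_pool))
            clauses.append(_comment_clause(c, surface, template, rng, style))
        if merge:
            sentences.append(_capitalize(clauses[0]) + ", and " + clauses[1] + ".")
        else:
            sentences.append(_capitalize(clauses[0]) + ".")
        i += len(group_comments)
    return sentences


def build_comments(
    panel: PanelResult,
    schema: PanelSchema,
    style: ReportStyle,
    rng: np.random.Generator,
) -> list[RenderedComment]:
    """Ground-truth comment list for a panel: one comment per abnormal
    (family, quantifier), with same-direction same-degree twins merged
    into a single compound comment with the style's probability."""
    abn = panel_abnormalities(panel, schema)
    per_family: dict[tuple[str, str], dict[Quantifier, Descriptor]] = {}
    order: list[tuple[str, str]] = []
    for aid, desc in abn:
        a = schema.analyte(aid)
        key = (a.group.value, a.family)
        if key not in per_family:
            per_family[key] = {}
            order.append(key)
        per_family[key][a.quantifier] = desc
    comments: list[RenderedComment] = []
    for key in order:
        group = Group(key[0])
        family = key[1]
        quals = per_family[key]
        both = (
            Quantifier.COUNT in quals
            and Quantifier.PERCENT in quals
            and quals[Quantifier.COUNT].direction == quals[Quantifier.PERCENT].direction
            and quals[Quantifier.COUNT].degree == quals[Quantifier.PERCENT].degree
        )
        if both and rng.random() < style.compound_prob:
            d = quals[Quantifier.COUNT]
            comments.append(
                RenderedComment(family, group, Quantifier.BOTH, d.direction, d.degree)
            )
            continue
        for q in (Quantifier.COUNT, Quantifier.PERCENT):
            if q in quals:
                comments.append(
                    RenderedComment(family, group, q, quals[q].direction, quals[q].degree)
                )
    return comments


def realize_report(
    panel: PanelResult,
    comments: list[RenderedComment],
    pbmc_present: bool,
    interp_sentences: list[str],
    aliases: AliasDictionary,
    style: ReportStyle,
    rng: np.random.Generator,
    attributes: Optional[dict[str, bool]] = None,
) -> Report:
    """Turn a comment list plus section flags into a concrete Report."""
    qlp = [c for c in comments if c.group == Group.QLP]
    bsp = [c for c in comments if c.group == Group.BSP]
    sections = [
        ReportSection(
            SectionLabel.QLP,
            _realize_comment_section(qlp, QLP_NORMAL_SENTENCE, aliases, style, rng),
        )
    ]
    if pbmc_present:
        sections.append(ReportSection(SectionLabel.PBMC, [PBMC_SENTENCE]))
    sections.append(
        ReportSection(
            SectionLabel.BSP,
            _realize_comment_section(bsp, BSP_NORMAL_SENTENCE, aliases, style, rng),
        )
    )
    if interp_sentences:
        sections.append(ReportSection(SectionLabel.INTERP, list(interp_sentences)))
    return Report(
        specimen_id=panel.specimen_id,
        sections=sections,
        comments=list(comments),
        attributes=attributes,
    )


def render_report(
    panel: PanelResult,
    schema: PanelSchema,
    style: str | ReportStyle = "harmonized",
    aliases: Optional[AliasDictionary] = None,
    checklist: Optional[AttributeChecklist] = None,
    pbmc_rule=None,
) -> Report:
    """Render the reference narrative report for a panel.

    Deterministic for a given (panel, style): all synonym and ordering
    choices derive from a seed hashed from the specimen id and style.
    """
    from .evaluation import pbmc_expected  # local import to avoid a cycle

    style = get_style(style)
    aliases = aliases or default_aliases()
    checklist = checklist or default_checklist()
    rng = np.random.default_rng(_render_seed(panel.specimen_id, style))
    comments = build_comments(panel, schema, style, rng)
    pbmc = pbmc_expected(panel, schema, pbmc_rule)
    attrs = panel_attributes(panel, schema, checklist, pbmc_expected=pbmc)
    interp = render_interpretation(attrs, checklist)
    return realize_report(panel, comments, pbmc, interp, aliases, style, rng, attrs)


# -- instruction / input / response tuples ----------------------------------


@dataclass(frozen=True)
class TrainingTuple:
    instruction: str
    input: str
    response: str
    specimen_id: str


def panel_to_text(panel: PanelResult, schema: PanelSchema) -> str:
    """Natural-language rendering of every analyte value with its descriptor."""
    phrases = []
    for a in schema.analytes:
        value = panel.values[a.analyte_id]
        if value is None:
            phrases.append(f"{a.display_name}: not reported")
            continue
        desc = classify_analyte(panel, schema, a.analyte_id)
        phrases.append(f"{a.display_name} {value:.1f} {a.units} ({desc.phrase()})")
    return "; ".join(phrases)


def make_training_tuple(
    panel: PanelResult,
    report: Report,
    schema: PanelSchema,
    instruction: str = DEFAULT_INSTRUCTION,
) -> TrainingTuple:
    if report.specimen_id != panel.specimen_id:
        raise ConsistencyError(
            f"report {report.specimen_id} does not belong to panel {panel.specimen_id}"
        )
    return TrainingTuple(
        instruction=instruction,
        input=panel_to_text(panel, schema),
        response=report.text,
        specimen_id=panel.specimen_id,
    )


# -- corruption --------------------------------------------------------------


class EditKind(str, enum.Enum):
    OMIT_COMMENT = "omit_comment"
    FLIP_DIRECTION = "flip_direction"
    SHIFT_DEGREE = "shift_degree"
    SWAP_QUANTIFIER = "swap_quantifier"
    HALLUCINATE_STATEMENT = "hallucinate_statement"


class CorruptionSpec(BaseModel):
    """Independent per-comment edit rates, all in [0, 1]."""

    omit_comment: float = Field(default=0.0, ge=0, le=1)
    flip_direction: float = Field(default=0.0, ge=0, le=1)
    shift_degree: float = Field(default=0.0, ge=0, le=1)
    swap_quantifier: float = Field(default=0.0, ge=0, le=1)
    hallucinate_statement: float = Field(default=0.0, ge=0, le=1)


@dataclass(frozen=True)
class CorruptionEdit:
    kind: EditKind
    family: str
    before: Optional[RenderedComment]
    after: Optional[RenderedComment]
    # position of the edited comment in the pre-corruption comment list
    # (None for hallucinated insertions)
    comment_index: Optional[int] = None


#: full record of the edits applied to one report
CorruptionLog = list


_FLIP = {Direction.DECREASED: Direction.INCREASED, Direction.INCREASED: Direction.DECREASED}
_SHIFT = {Degree.MILD: Degree.MODERATE, Degree.MODERATE: Degree.SIGNIFICANT, Degree.SIGNIFICANT: Degree.MODERATE}
_SWAP = {Quantifier.COUNT: Quantifier.PERCENT, Quantifier.PERCENT: Quantifier.COUNT, Quantifier.BOTH: Quantifier.COUNT}


def corrupt_report(
    report: Report,
    panel: PanelResult,
    schema: PanelSchema,
    spec: CorruptionSpec,
    seed: int,
    style: str | ReportStyle = "harmonized",
    aliases: Optional[AliasDictionary] = None,
) -> tuple[Report, CorruptionLog]:
    """Apply seeded edits to a report's abnormality comments.

    Every edit is logged with its before/after statement, so evaluation
    deficits of the corrupted report are exactly predictable by replaying
    the log in statement space (:func:`apply_corruption_log`).  PBMC and
    interpretation sections are carried over unchanged.
    """
    style = get_style(style)
    aliases = aliases or default_aliases()
    rng = np.random.default_rng(seed)
    log: CorruptionLog = []
    edited: list[RenderedComment] = []
    for pos, c in enumerate(report.comments):
        if rng.random() < spec.omit_comment:
            log.append(CorruptionEdit(EditKind.OMIT_COMMENT, c.family, c, None, pos))
            continue
        cur = c
        if rng.random() < spec.flip_direction:
            nxt = replace(cur, direction=_FLIP[cur.direction])
            log.append(CorruptionEdit(EditKind.FLIP_DIRECTION, cur.family, cur, nxt, pos))
            cur = nxt
        if rng.random() < spec.shift_degree:
            nxt = replace(cur, degree=_SHIFT[cur.degree])
            log.append(CorruptionEdit(EditKind.SHIFT_DEGREE, cur.family, cur, nxt, pos))
            cur = nxt
        if rng.random() < spec.swap_quantifier:
            nxt = replace(cur, quantifier=_SWAP[cur.quantifier])
            log.append(CorruptionEdit(EditKind.SWAP_QUANTIFIER, cur.family, cur, nxt, pos))
            cur = nxt
        edited.append(cur)
    # Hallucinations: per original comment, insert a claim about a cell
    # family with no laboratory abnormality on the claimed analyte.
    in_range = [
        a
        for a in schema.analytes
        if panel.values[a.analyte_id] is not None
        and not classify_analyte(panel, schema, a.analyte_id).abnormal
    ]
    for _ in range(len(report.comments)):
        if not in_range or rng.random() >= spec.hallucinate_statement:
            continue
        idx = int(rng.integers(len(in_range)))
        a = in_range.pop(idx)
        fake = RenderedComment(
            family=a.family,
            group=a.group,
            quantifier=a.quantifier,
            direction=Direction.DECREASED if rng.random() < 0.5 else Direction.INCREASED,
            degree=(Degree.MILD, Degree.MODERATE, Degree.SIGNIFICANT)[int(rng.integers(3))],
        )
        edited.append(fake)
        log.append(CorruptionEdit(EditKind.HALLUCINATE_STATEMENT, a.family, None, fake))
    pbmc_section = report.section(SectionLabel.PBMC)
    interp_section = report.section(SectionLabel.INTERP)
    corrupted = realize_report(
        panel,
        edited,
        pbmc_present=pbmc_section is not None,
        interp_sentences=list(interp_section.sentences) if interp_section else [],
        aliases=aliases,
        style=style,
        rng=np.random.default_rng(seed + 1),
        attributes=copy.deepcopy(report.attributes),
    )
    return corrupted, log


def apply_corruption_log(
    comments: list[RenderedComment], log: CorruptionLog
) -> list[RenderedComment]:
    """Replay an edit log against the pre-corruption comment list.

    This is the statement-space route used to predict metric deficits
    independently of text rendering and re-extraction.
    """
    current: dict[int, RenderedComment] = dict(enumerate(comments))
    inserted: list[RenderedComment] = []
    for edit in log:
        if edit.kind == EditKind.HALLUCINATE_STATEMENT:
            inserted.append(edit.after)
            continue
        if current.get(edit.comment_index) != edit.before:
            raise ValueError(
                f"log does not match comment list at index {edit.comment_index}"
            )
        if edit.kind == EditKind.OMIT_COMMENT:
            current.pop(edit.comment_index)
        else:
            current[edit.comment_index] = edit.after
    return [current[i] for i in sorted(current)] + inserted
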