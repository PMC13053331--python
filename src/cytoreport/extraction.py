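"""Structured-statement extraction from QLP/BSP narrative sentences.

Each sentence of a QLP or BSP comment section is parsed into zero or more
``ExtractedStatement`` tuples (cell type, direction, degree, quantifier).
Cell-type surface forms are normalized to canonical family keys through a
many-to-one alias dictionary; direction, degree, and quantifier come from
closed cue lexicons attached to each alias mention's clause.  The default
extractor is deterministic and rule-based; any callable with the same
signature (an LLM-backed adapter, for instance) can stand in for it, as
long as it emits the same statement type.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import ConfigError
from .panel import Degree, Direction, Quantifier

try:
    from importlib import resources as _resources
except ImportError:  # pragma: no cover
    import importlib_resources as _resources  # type: ignore

#: Sentinel returned by :func:`normalize_alias` when a term is unknown.
NO_MATCH = None


@dataclass(frozen=True)
class ExtractedStatement:
    """A normalized narrative claim about one cell family."""

    cell_type: str
    direction: Direction
    degree: Degree
    quantifier: Quantifier
    source_sentence_index: int = -1

    @property
    def abnormal(self) -> bool:
        return self.direction != Direction.NORMAL

    def key(self) -> tuple:
        return (self.cell_type, self.quantifier.value, self.direction.value, self.degree.value)


# Cue lexicons.  Word -> canonical value; matched on normalized text.
DIRECTION_WORDS: dict[str, Direction] = {
    "decreased": Direction.DECREASED,
    "reduced": Direction.DECREASED,
    "diminished": Direction.DECREASED,
    "low": Direction.DECREASED,
    "depressed": Direction.DECREASED,
    "increased": Direction.INCREASED,
    "elevated": Direction.INCREASED,
    "expanded": Direction.INCREASED,
    "high": Direction.INCREASED,
    "raised": Direction.INCREASED,
}

DEGREE_WORDS: dict[str, Degree] = {
    "mildly": Degree.MILD,
    "mild": Degree.MILD,
    "slightly": Degree.MILD,
    "moderately": Degree.MODERATE,
    "moderate": Degree.MODERATE,
    "significantly": Degree.SIGNIFICANT,
    "significant": Degree.SIGNIFICANT,
    "markedly": Degree.SIGNIFICANT,
    "marked": Degree.SIGNIFICANT,
    "severely": Degree.SIGNIFICANT,
}

_NORMAL_RE = re.compile(
    r"\bwithin (?:the )?(?:institutional )?(?:reference|normal) (?:range|ranges|limits|intervals)\b"
    r"|\bwithin normal limits\b|\bnormal\b|\bunremarkable\b"
)
_NEGATION_RE = re.compile(r"\b(?:no|not|without|neither)\b")

_BOTH_RE = re.compile(
    r"\b(?:absolute )?counts? and (?:relative )?percentages?\b"
    r"|\bpercentages? and (?:absolute )?counts?\b"
)
_COUNT_RE = re.compile(r"\babsolute counts?\b|\bcounts?\b|\babsolute numbers?\b")
_PERCENT_RE = re.compile(r"\bpercentages?\b|\bpercent\b|\brelative frequenc(?:y|ies)\b")


def normalize_text(text: str) -> str:
    """Case-fold and strip the punctuation variation aliases may carry.

    Hyphens become spaces, ``+`` markers are dropped, accents are removed,
    and whitespace is collapsed, so that lookup is insensitive to surface
    typography (``Switched-Memory`` == ``switched memory``).
    """
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    text = text.casefold()
    text = text.replace("-", " ").replace("+", "")
    text = re.sub(r"\s+", " ", text).strip()
    return text


@dataclass
class AliasDictionary:
    """Many-to-one map from surface cell-type phrases to canonical family keys."""

    mapping: dict[str, str]  # normalized surface -> canonical key
    surfaces: dict[str, list[str]] = field(default_factory=dict)  # canonical -> raw surfaces
    direction_words: dict[str, Direction] = field(default_factory=lambda: dict(DIRECTION_WORDS))
    degree_words: dict[str, Degree] = field(default_factory=lambda: dict(DEGREE_WORDS))
    _patterns: list[tuple[re.Pattern, str]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        # Longest surface first so that e.g. "switched memory b cells" wins
        # over the embedded "memory b cells".
        for surface in sorted(self.mapping, key=len, reverse=True):
            pat = re.compile(r"(?<!\w)" + re.escape(surface) + r"(?!\w)")
            self._patterns.append((pat, self.mapping[surface]))

    @property
    def canonical_keys(self) -> set[str]:
        return set(self.mapping.values())

    def preferred_surface(self, canonical: str) -> str:
        return self.surfaces[canonical][0]

    def surface_pool(self, canonical: str, n: int) -> list[str]:
        pool = self.surfaces.get(canonical, [canonical])
        return pool[: max(1, n)]


def load_aliases(path: str | Path) -> AliasDictionary:
    """Read an alias dictionary from a two-column CSV (surface, canonical)."""
    mapping: dict[str, str] = {}
    surfaces: dict[str, list[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or {"surface", "canonical"} - set(reader.fieldnames):
            raise ConfigError(f"{path}: alias CSV needs 'surface' and 'canonical' columns")
        for row in reader:
            surface, canonical = row["surface"].strip(), row["canonical"].strip()
            if not surface or not canonical:
                continue
            mapping[normalize_text(surface)] = canonical
            surfaces.setdefault(canonical, []).append(surface)
    if not mapping:
        raise ConfigError(f"{path}: empty alias dictionary")
    return AliasDictionary(mapping=mapping, surfaces=surfaces)


def default_aliases() -> AliasDictionary:
    """Bundled alias dictionary covering the default schema's cell families."""
    with _resources.as_file(
        _resources.files("cytoreport.data").joinpath("aliases.csv")
    ) as p:
        return load_aliases(p)


def normalize_alias(term: str, aliases: AliasDictionary) -> Optional[str]:
    """Canonical family key for a surface term, or :data:`NO_MATCH`.

    Lookup is case-, whitespace-, and hyphen-insensitive and never guesses:
    an unknown term maps to the explicit no-match sentinel.  Canonical keys
    are fixed points, so normalization is idempotent.
    """
    norm = normalize_text(term)
    hit = aliases.mapping.get(norm)
    if hit is not None:
        return hit
    if term in aliases.canonical_keys:
        return term
    return NO_MATCH


def _find_alias_spans(norm: str, aliases: AliasDictionary) -> list[tuple[int, int, str]]:
    """Non-overlapping alias matches, longest-match-first, sorted by position."""
    taken: list[tuple[int, int, str]] = []
    for pat, canonical in aliases._patterns:
        for m in pat.finditer(norm):
            s, e = m.span()
            if any(s < te and ts < e for ts, te, _ in taken):
                continue
            taken.append((s, e, canonical))
    return sorted(taken)


def _first(regex: re.Pattern, text: str) -> Optional[re.Match]:
    return regex.search(text)


def _scope_direction(scope: str) -> Optional[Direction]:
    hits: list[tuple[int, Direction]] = []
    for word, direction in DIRECTION_WORDS.items():
        for m in re.finditer(rf"\b{word}\b", scope):
            # A negated direction cue ("not decreased") asserts normality.
            prefix = scope[max(0, m.start() - 12) : m.start()]
            if _NEGATION_RE.search(prefix):
                return Direction.NORMAL
            hits.append((m.start(), direction))
    if hits:
        return min(hits)[1]
    if re.search(r"\bno abnormalit(?:y|ies)\b", scope) or _NORMAL_RE.search(scope):
        return Direction.NORMAL
    return None


def _scope_degree(scope: str) -> Optional[Degree]:
    hits = [
        (m.start(), degree)
        for word, degree in DEGREE_WORDS.items()
        for m in re.finditer(rf"\b{word}\b", scope)
    ]
    return min(hits)[1] if hits else None


def _scope_quantifier(scope: str) -> Quantifier:
    both = _BOTH_RE.search(scope)
    if both:
        return Quantifier.BOTH
    count = _COUNT_RE.search(scope)
    percent = _PERCENT_RE.search(scope)
    if count and percent:
        # Both cues without a conjunction: take the earlier mention.
        return Quantifier.COUNT if count.start() < percent.start() else Quantifier.PERCENT
    if count:
        return Quantifier.COUNT
    if percent:
        return Quantifier.PERCENT
    return Quantifier.UNSPECIFIED


def extract_statements(
    sentence: str,
    aliases: AliasDictionary,
    sentence_index: int = -1,
) -> list[ExtractedStatement]:
    """Rule-based extraction of structured statements from one sentence.

    Alias mentions are located longest-match-first; each mention's cue
    scope runs from the mention to the next mention (the whole sentence
    when it is the only mention, since templates may lead with the
    quantifier: "The percentage of X is ...").  Sentences with no alias
    mention return an empty list.
    """
    norm = normalize_text(sentence)
    spans = _find_alias_spans(norm, aliases)
    if not spans:
        return []
    # Mentions are excluded from cue search so that surface forms containing
    # cue-like tokens ("CD21-low") cannot self-assert a direction.
    blanked = list(norm)
    for s, e, _ in spans:
        blanked[s:e] = " " * (e - s)
    blanked_norm = "".join(blanked)
    statements: list[ExtractedStatement] = []
    for i, (start, end, canonical) in enumerate(spans):
        if len(spans) == 1:
            scope = blanked_norm
        else:
            scope_end = spans[i + 1][0] if i + 1 < len(spans) else len(norm)
            scope = blanked_norm[end:scope_end]
        direction = _scope_direction(scope)
        if direction is None and len(spans) > 1:
            direction = _scope_direction(blanked_norm)
        if direction is None:
            continue  # mention without any claim
        if direction == Direction.NORMAL:
            degree = Degree.NONE
        else:
            degree = _scope_degree(scope) or Degree.UNSPECIFIED
        quantifier = _scope_quantifier(scope)
        statements.append(
            ExtractedStatement(
                cell_type=canonical,
                direction=direction,
                degree=degree,
                quantifier=quantifier,
                source_sentence_index=sentence_index,
            )
        )
    return statements


def extract_report_statements(report, aliases: AliasDictionary) -> list[ExtractedStatement]:
    """Extract statements from every QLP/BSP sentence of a rendered report."""
    from .reporting import SectionLabel  # local import to avoid a cycle

    out: list[ExtractedStatement] = []
    for idx, label, sentence in report.iter_sentences():
        if label in (SectionLabel.QLP, SectionLabel.BSP):
            out.extend(extract_statements(sentence, aliases, sentence_index=idx))
    return out
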