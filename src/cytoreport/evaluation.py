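"""Concordance metrics for narrative comments against a reference standard.

Four complementary metrics summarize how faithfully a report's QLP/BSP
comments track the reference abnormalities:

* comment rate — fraction of reference abnormalities mentioned at all;
* direction accuracy — increased vs decreased, over commented abnormalities;
* degree accuracy — mild/moderate/significant concordance, over commented
  abnormalities whose statement specifies a magnitude;
* quantifier accuracy — whether a commented family's abnormalities were
  framed as counts, percentages, or both, matching the reference framing.

Metrics run under two reference standards: the raw laboratory values
(every out-of-range analyte is a reference abnormality) or a reference
report's own abnormality statements (concordance with what the reference
author chose to comment on).  Statements about analytes with no reference
abnormality are unsupported (false positives); reference abnormalities
with no statement are omissions (false negatives).  Zero-denominator
metrics are an explicit ``None`` sentinel, never interpolated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel
from scipy import stats as _scipy_stats
from statsmodels.stats.multitest import multipletests

from .errors import SchemaError, UsageError
from .extraction import ExtractedStatement
from .panel import (
    Degree,
    Direction,
    PanelResult,
    PanelSchema,
    Quantifier,
    classify_analyte,
    panel_abnormalities,
)

#: Explicit sentinel for metrics with an empty denominator.
UNDEFINED = None


class ReferenceStandard(str, enum.Enum):
    LAB_VALUES = "lab"
    REFERENCE_REPORT = "reference"


@dataclass
class CellTally:
    """Per-(family, quantifier) bookkeeping for one report."""

    n_abnormal: int = 0
    n_commented: int = 0
    n_direction_correct: int = 0
    n_degree_eval: int = 0
    n_degree_correct: int = 0
    n_unsupported: int = 0

    @property
    def n_omitted(self) -> int:
        return self.n_abnormal - self.n_commented


@dataclass
class EvalRecord:
    """Evaluation of one report against one reference standard."""

    specimen_id: str
    standard: ReferenceStandard
    per_cell: dict[tuple[str, str], CellTally] = field(default_factory=dict)
    # family -> (claimed quantifier framing matches reference framing)
    quantifier_correct: dict[str, bool] = field(default_factory=dict)

    def _sum(self, attr: str) -> int:
        return sum(getattr(t, attr) for t in self.per_cell.values())

    @property
    def n_abnormal(self) -> int:
        return self._sum("n_abnormal")

    @property
    def n_commented(self) -> int:
        return self._sum("n_commented")

    @property
    def n_unsupported(self) -> int:
        return self._sum("n_unsupported")

    @property
    def n_omitted(self) -> int:
        return self.n_abnormal - self.n_commented

    @property
    def n_quantifier_correct(self) -> int:
        return sum(self.quantifier_correct.values())

    @property
    def comment_rate(self) -> Optional[float]:
        return self.n_commented / self.n_abnormal if self.n_abnormal else UNDEFINED

    @property
    def direction_accuracy(self) -> Optional[float]:
        n = self.n_commented
        return self._sum("n_direction_correct") / n if n else UNDEFINED

    @property
    def degree_accuracy(self) -> Optional[float]:
        n = self._sum("n_degree_eval")
        return self._sum("n_degree_correct") / n if n else UNDEFINED

    @property
    def quantifier_accuracy(self) -> Optional[float]:
        n = len(self.quantifier_correct)
        return self.n_quantifier_correct / n if n else UNDEFINED

    def summary(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "standard": self.standard.value,
            "n_abnormal": self.n_abnormal,
            "n_commented": self.n_commented,
            "n_unsupported": self.n_unsupported,
            "n_omitted": self.n_omitted,
            "comment_rate": self.comment_rate,
            "direction_accuracy": self.direction_accuracy,
            "degree_accuracy": self.degree_accuracy,
            "quantifier_accuracy": self.quantifier_accuracy,
        }


_DEG_ORDER = {d: i for i, d in enumerate(Degree)}
_DIR_ORDER = {d: i for i, d in enumerate(Direction)}


def _expand_units(
    statements: Sequence[ExtractedStatement],
) -> dict[tuple[str, Quantifier], tuple[Direction, Degree]]:
    """Abnormal statements as claimed (family, quantifier) units.

    ``both`` expands to the count and percent twin units.  When several
    statements claim the same unit, the claim kept is the lexicographically
    smallest (direction, degree) — a deterministic rule that does not
    depend on sentence order.
    """
    claims: dict[tuple[str, Quantifier], list[tuple[int, int, Direction, Degree]]] = {}
    for s in statements:
        if s.direction == Direction.NORMAL:
            continue
        quants = (
            (Quantifier.COUNT, Quantifier.PERCENT)
            if s.quantifier == Quantifier.BOTH
            else (s.quantifier,)
        )
        for q in quants:
            claims.setdefault((s.cell_type, q), []).append(
                (_DIR_ORDER[s.direction], _DEG_ORDER[s.degree], s.direction, s.degree)
            )
    return {unit: min(cands)[2:] for unit, cands in claims.items()}


def evaluate_report(
    statements: Sequence[ExtractedStatement],
    panel: PanelResult,
    schema: PanelSchema,
    standard: ReferenceStandard = ReferenceStandard.LAB_VALUES,
    reference_statements: Optional[Sequence[ExtractedStatement]] = None,
) -> EvalRecord:
    """Score one report's statements against the chosen reference standard.

    The statement-to-abnormality join key is (canonical cell family,
    quantifier); a statement framed as ``both`` matches either twin.
    Unmatched abnormal statements are unsupported; unmatched reference
    abnormalities are omitted.
    """
    if standard == ReferenceStandard.REFERENCE_REPORT and reference_statements is None:
        raise UsageError("REFERENCE_REPORT standard requires reference_statements")

    if standard == ReferenceStandard.LAB_VALUES:
        reference: dict[tuple[str, Quantifier], tuple[Direction, Degree]] = {}
        for aid, desc in panel_abnormalities(panel, schema):
            a = schema.analyte(aid)
            reference[(a.family, a.quantifier)] = (desc.direction, desc.degree)
    else:
        reference = _expand_units(reference_statements)

    claimed = _expand_units(statements)

    record = EvalRecord(specimen_id=panel.specimen_id, standard=standard)
    for (family, quant), (ref_dir, ref_deg) in reference.items():
        tally = record.per_cell.setdefault((family, quant.value), CellTally())
        tally.n_abnormal += 1
        claim = claimed.get((family, quant))
        if claim is None:
            continue
        c_dir, c_deg = claim
        tally.n_commented += 1
        if c_dir == ref_dir:
            tally.n_direction_correct += 1
        # Degree is judged only when both the claim and the reference
        # specify a magnitude; unspecified degrees still count as comments.
        if c_deg not in (Degree.UNSPECIFIED, Degree.NONE) and ref_deg not in (
            Degree.UNSPECIFIED,
            Degree.NONE,
        ):
            tally.n_degree_eval += 1
            if c_deg == ref_deg:
                tally.n_degree_correct += 1
    for unit, _claim in claimed.items():
        if unit not in reference:
            family, quant = unit
            tally = record.per_cell.setdefault((family, quant.value), CellTally())
            tally.n_unsupported += 1

    # Quantifier framing, per commented family: the reference framing is
    # the set of abnormal twins; the claimed framing is the set of claimed
    # quantifiers for that family (count+percent == both).
    ref_by_family: dict[str, set[Quantifier]] = {}
    for family, quant in reference:
        ref_by_family.setdefault(family, set()).add(quant)
    claimed_by_family: dict[str, set[Quantifier]] = {}
    for family, quant in claimed:
        claimed_by_family.setdefault(family, set()).add(quant)
    for family, ref_quants in ref_by_family.items():
        commented = any(
            record.per_cell.get((family, q.value), CellTally()).n_commented for q in ref_quants
        )
        if not commented:
            continue
        record.quantifier_correct[family] = claimed_by_family.get(family, set()) == ref_quants
    return record


# -- PBMC logical check -----------------------------------------------------


class PbmcClause(BaseModel):
    analyte_id: str
    condition: str = "abnormal"  # abnormal | below | above


class PbmcRule(BaseModel):
    """Disjunction of per-analyte conditions deciding whether a PBMC
    comment is expected."""

    any_of: list[PbmcClause]


DEFAULT_PBMC_RULE = PbmcRule(
    any_of=[
        PbmcClause(analyte_id="CD19_CT", condition="abnormal"),
        PbmcClause(analyte_id="CD20_CT", condition="abnormal"),
    ]
)


def pbmc_expected(
    panel: PanelResult, schema: PanelSchema, rule: Optional[PbmcRule] = None
) -> bool:
    """Whether the panel's CD19+/CD20+ counts call for a PBMC comment.

    The default rule fires when either absolute count is outside its
    reference range; any predicate over analyte descriptors can be
    configured instead.
    """
    rule = rule or DEFAULT_PBMC_RULE
    for clause in rule.any_of:
        schema.analyte(clause.analyte_id)  # raises SchemaError if absent
        desc = classify_analyte(panel, schema, clause.analyte_id)
        if desc is None:
            continue
        if clause.condition == "abnormal" and desc.abnormal:
            return True
        if clause.condition == "below" and desc.direction == Direction.DECREASED:
            return True
        if clause.condition == "above" and desc.direction == Direction.INCREASED:
            return True
        if clause.condition not in ("abnormal", "below", "above"):
            raise UsageError(f"unknown PBMC condition: {clause.condition}")
    return False


class PbmcOutcome(str, enum.Enum):
    MATCH = "match"
    MISSING_COMMENT = "missing_comment"
    UNSUPPORTED_COMMENT = "unsupported_comment"


def pbmc_check(
    report, panel: PanelResult, schema: PanelSchema, rule: Optional[PbmcRule] = None
) -> PbmcOutcome:
    """Compare presence of a PBMC-labeled sentence with the expected flag."""
    from .reporting import SectionLabel

    expected = pbmc_expected(panel, schema, rule)
    section = report.section(SectionLabel.PBMC)
    present = section is not None and bool(section.sentences)
    if expected == present:
        return PbmcOutcome.MATCH
    return PbmcOutcome.MISSING_COMMENT if expected else PbmcOutcome.UNSUPPORTED_COMMENT


# -- error rates and correlation --------------------------------------------


def error_rate(n_errors: int, n_statements: int) -> Optional[float]:
    """Percentage of erroneous statements, to one decimal; None when the
    denominator is zero."""
    if n_statements <= 0:
        return UNDEFINED
    return round(100.0 * n_errors / n_statements, 1)


def format_error_rate(n_errors: int, n_statements: int) -> str:
    rate = error_rate(n_errors, n_statements)
    if rate is UNDEFINED:
        return f"undefined(0/{n_statements})"
    return f"{rate}%({n_errors}/{n_statements})"


@dataclass
class CorrelationResult:
    r: Optional[float]
    n_used: int
    excluded: list[int]
    method: str = "pearson"


def prevalence_correlation(
    table: Sequence[tuple[float, Optional[float]]], method: str = "pearson"
) -> CorrelationResult:
    """Correlation between per-cell-type abnormality counts and comment rates.

    Cell types whose comment rate is undefined (zero abnormalities in the
    corpus) are excluded and reported.  Fewer than three usable points, or
    zero variance on either axis, yield the undefined sentinel.
    """
    excluded = [i for i, (_, rate) in enumerate(table) if rate is UNDEFINED]
    pts = [(c, r) for c, r in table if r is not UNDEFINED]
    if len(pts) < 3:
        return CorrelationResult(UNDEFINED, len(pts), excluded, method)
    counts = np.asarray([p[0] for p in pts], dtype=float)
    rates = np.asarray([p[1] for p in pts], dtype=float)
    if np.ptp(counts) == 0 or np.ptp(rates) == 0:
        return CorrelationResult(UNDEFINED, len(pts), excluded, method)
    if method == "pearson":
        r = float(_scipy_stats.pearsonr(counts, rates).statistic)
    elif method == "spearman":
        r = float(_scipy_stats.spearmanr(counts, rates).statistic)
    else:
        raise UsageError(f"unknown correlation method: {method}")
    return CorrelationResult(r, len(pts), excluded, method)


# -- method comparison harness ----------------------------------------------


@dataclass
class PairwiseTest:
    method_a: str
    method_b: str
    statistic: float
    p_raw: float
    p_adj: float


@dataclass
class MethodComparison:
    methods: list[str]
    paired: bool
    friedman_statistic: Optional[float]
    friedman_p: Optional[float]
    pairwise: list[PairwiseTest]


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (statsmodels fdr_bh)."""
    if len(pvalues) == 0:
        return []
    _, adj, _, _ = multipletests(list(pvalues), method="fdr_bh")
    return [float(p) for p in adj]


def compare_methods(
    tables: Mapping[str, Sequence[float]], paired: bool
) -> MethodComparison:
    """Rank-based comparison of per-cell-type metric tables across methods.

    Paired data use the Wilcoxon signed-rank test (zsplit zero handling,
    so identical samples yield the null-centered statistic n(n+1)/4);
    unpaired data use the rank-sum (Mann-Whitney) test.  With more than
    two methods a Friedman omnibus precedes the pairwise tests, whose
    p-values are Benjamini-Hochberg corrected.
    """
    methods = list(tables)
    if len(methods) < 2:
        raise UsageError("compare_methods needs at least two methods")
    arrays = {m: np.asarray(tables[m], dtype=float) for m in methods}
    if paired:
        sizes = {arr.size for arr in arrays.values()}
        if len(sizes) != 1:
            raise UsageError(f"paired tables must align on cell types, got sizes {sizes}")
    friedman_stat = friedman_p = None
    if paired and len(methods) > 2:
        friedman_stat, friedman_p = _scipy_stats.friedmanchisquare(
            *[arrays[m] for m in methods]
        )
        friedman_stat, friedman_p = float(friedman_stat), float(friedman_p)
    pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1 :]]
    raw: list[tuple[str, str, float, float]] = []
    for a, b in pairs:
        x, y = arrays[a], arrays[b]
        if paired:
            res = _scipy_stats.wilcoxon(x, y, zero_method="zsplit")
        else:
            res = _scipy_stats.mannwhitneyu(x, y, alternative="two-sided")
        raw.append((a, b, float(res.statistic), float(res.pvalue)))
    adjusted = benjamini_hochberg([p for *_, p in raw])
    pairwise = [
        PairwiseTest(a, b, stat, p, p_adj)
        for (a, b, stat, p), p_adj in zip(raw, adjusted)
    ]
    return MethodComparison(methods, paired, friedman_stat, friedman_p, pairwise)
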