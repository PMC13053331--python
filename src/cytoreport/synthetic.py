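"""Synthetic QLP/BSP cohort generation.

Panels are drawn so that every downstream stage (rendering, labeling,
extraction, evaluation) is testable without clinical data.  For each
analyte an abnormality indicator is drawn, then a direction (below/above
the range) and a degree stratum (mild/moderate/significant); the numeric
value is sampled uniformly within the excursion interval that the degree
cutpoints map back to that stratum, so generator and classifier are exact
inverses by construction.  Count/percent twins co-deviate with a
configurable pairing correlation, mimicking the coupling between absolute
and relative abnormalities in real panels.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import DomainError
from .panel import (
    Degree,
    Direction,
    PanelResult,
    PanelSchema,
    Quantifier,
    ReferenceRange,
)

# Margin keeping sampled excursions strictly inside their stratum interval,
# so float round-trip through the classifier cannot cross a cutpoint.
_EDGE = 1e-3


class CohortProfile(BaseModel):
    """Sampling profile for a synthetic cohort.

    ``abnormality_prob`` may be a single probability or a per-analyte
    mapping; ``class_mix`` optionally defines panel-level strata as
    (weight, probability-scale) pairs, which lets a cohort combine a
    mostly-normal subpopulation with a high-abnormality one — real
    referral cohorts are overdispersed in exactly this way.
    """

    n: int = Field(gt=0)
    abnormality_prob: float | dict[str, float] = 0.2
    below_fraction: float = Field(default=0.5, ge=0, le=1)
    degree_mix: tuple[float, float, float] = (0.55, 0.30, 0.15)
    pairing_correlation: float = Field(default=0.4, ge=0, le=1)
    class_mix: Optional[list[tuple[float, float]]] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortProfile":
        if abs(sum(self.degree_mix) - 1.0) > 1e-9:
            raise ValueError(f"degree_mix must sum to 1, got {self.degree_mix}")
        if any(p < 0 for p in self.degree_mix):
            raise ValueError("degree_mix probabilities must be non-negative")
        probs = (
            self.abnormality_prob.values()
            if isinstance(self.abnormality_prob, dict)
            else [self.abnormality_prob]
        )
        for p in probs:
            if not 0 <= p <= 1:
                raise ValueError(f"abnormality probability outside [0,1]: {p}")
        if self.class_mix is not None:
            weights = [w for w, _ in self.class_mix]
            if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError("class_mix weights must be non-negative and sum to 1")
        return self

    def prob_for(self, analyte_id: str) -> float:
        if isinstance(self.abnormality_prob, dict):
            return self.abnormality_prob.get(analyte_id, 0.0)
        return self.abnormality_prob


def table1_profile(n: int = 500, seed: int = 0) -> CohortProfile:
    """Bundled cohort profile emulating a referral population's abnormality
    structure: most panels carry at least one out-of-range result, with a
    median of roughly seven abnormal findings among abnormal panels, and a
    minority subpopulation that is essentially normal."""
    return CohortProfile(
        n=n,
        abnormality_prob=0.22,
        below_fraction=0.6,
        degree_mix=(0.55, 0.30, 0.15),
        pairing_correlation=0.4,
        class_mix=[(0.87, 1.0), (0.13, 0.03)],
        seed=seed,
    )


def _degree_interval(
    degree: Degree, mild: float, significant: float, cap: float
) -> tuple[float, float]:
    """Excursion interval (lo, hi) that classifies back to ``degree``."""
    if degree == Degree.MILD:
        lo, hi = 0.0, min(mild, cap)
    elif degree == Degree.MODERATE:
        lo, hi = mild, min(significant, cap)
    else:
        lo, hi = significant, min(2.0 * significant, cap)
    if hi <= lo:
        raise DomainError(
            f"degree stratum {degree.value} unreachable: thresholds vs cap {cap}"
        )
    return lo, hi


def _sample_value(
    rng: np.random.Generator,
    ref: ReferenceRange,
    direction: Direction,
    degree: Degree,
    mild: float,
    significant: float,
) -> float:
    if direction == Direction.NORMAL:
        return float(rng.uniform(ref.lower, ref.upper))
    if direction == Direction.DECREASED:
        # value = lower * (1 - d); d can reach at most 1 (value 0).
        lo, hi = _degree_interval(degree, mild, significant, cap=1.0)
    else:
        lo, hi = _degree_interval(degree, mild, significant, cap=2.0 * significant)
    span = hi - lo
    d = lo + span * (_EDGE + (1.0 - 2.0 * _EDGE) * rng.random())
    if direction == Direction.DECREASED:
        return float(ref.lower * (1.0 - d))
    return float(ref.upper * (1.0 + d))


def _draw_state(
    rng: np.random.Generator,
    prob: float,
    profile: CohortProfile,
    can_decrease: bool,
) -> Optional[tuple[Direction, Degree]]:
    """Abnormality state for one analyte: None (in range) or (direction, degree)."""
    if rng.random() >= prob:
        return None
    below = rng.random() < profile.below_fraction
    if below and not can_decrease:
        below = False  # a range with lower == 0 cannot be undershot
    direction = Direction.DECREASED if below else Direction.INCREASED
    idx = rng.choice(3, p=np.asarray(profile.degree_mix, dtype=float))
    degree = (Degree.MILD, Degree.MODERATE, Degree.SIGNIFICANT)[int(idx)]
    return direction, degree


def generate_panel(
    profile: CohortProfile,
    schema: PanelSchema,
    rng: np.random.Generator,
    specimen_id: str = "SYN-0",
    patient_age: float = 37.0,
    prob_scale: float = 1.0,
) -> PanelResult:
    """Draw one panel.

    Count/percent twins are processed together: with probability equal to
    the pairing correlation the percent twin copies the count twin's
    abnormality state (direction and degree stratum), otherwise it draws
    independently.  Values land strictly inside their sampled stratum.
    """
    mild, significant = schema.thresholds.mild, schema.thresholds.significant
    values: dict[str, Optional[float]] = {}
    done: set[str] = set()
    for a in schema.analytes:
        if a.analyte_id in done:
            continue
        twin = schema.analyte(a.paired_analyte_id) if a.paired_analyte_id else None
        # Lead with the count analyte of the pair for a stable draw order.
        first, second = a, twin
        if twin is not None and a.quantifier != Quantifier.COUNT:
            first, second = twin, a
        ref1 = schema.range_for(first.analyte_id, patient_age)
        p1 = min(1.0, profile.prob_for(first.analyte_id) * prob_scale)
        state1 = _draw_state(rng, p1, profile, can_decrease=ref1.lower > 0)
        values[first.analyte_id] = _sample_value(
            rng, ref1, *(state1 or (Direction.NORMAL, Degree.NONE)), mild, significant
        )
        done.add(first.analyte_id)
        if second is None:
            continue
        ref2 = schema.range_for(second.analyte_id, patient_age)
        if rng.random() < profile.pairing_correlation:
            state2 = state1
            if state2 is not None and state2[0] == Direction.DECREASED and ref2.lower == 0:
                state2 = (Direction.INCREASED, state2[1])
        else:
            p2 = min(1.0, profile.prob_for(second.analyte_id) * prob_scale)
            state2 = _draw_state(rng, p2, profile, can_decrease=ref2.lower > 0)
        values[second.analyte_id] = _sample_value(
            rng, ref2, *(state2 or (Direction.NORMAL, Degree.NONE)), mild, significant
        )
        done.add(second.analyte_id)
    return PanelResult(specimen_id=specimen_id, patient_age=patient_age, values=values)


def generate_cohort(profile: CohortProfile, schema: PanelSchema) -> list[PanelResult]:
    """Draw ``profile.n`` panels, reproducibly from ``profile.seed``."""
    if profile.n <= 0:  # pydantic enforces this; double-check for dict callers
        raise DomainError(f"cohort size must be positive, got {profile.n}")
    rng = np.random.default_rng(profile.seed)
    class_mix = profile.class_mix or [(1.0, 1.0)]
    weights = np.asarray([w for w, _ in class_mix], dtype=float)
    scales = [s for _, s in class_mix]
    panels = []
    for i in range(profile.n):
        k = int(rng.choice(len(scales), p=weights))
        panels.append(
            generate_panel(
                profile,
                schema,
                rng,
                specimen_id=f"SYN-{i:06d}",
                prob_scale=scales[k],
            )
        )
    return panels
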