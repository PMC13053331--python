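"""Unsupervised retrieval baseline: predict a report from laboratory values.

A corpus of prior (panel, report) pairs is indexed by z-scored laboratory
feature vectors; a query panel retrieves either the whole report of its
nearest corpus neighbor or, section by section, the matching section of
the nearest neighbor that has that section (reports are assembled from
previously authored interpretations).  Similarity is cosine on the
standardized features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import SchemaError, UsageError
from .panel import PanelResult, PanelSchema, validate_panel
from .reporting import Report, ReportSection, SECTION_ORDER


@dataclass
class Standardization:
    analyte_ids: list[str]
    center: np.ndarray
    scale: np.ndarray


@dataclass
class RetrievalIndex:
    standardization: Standardization
    matrix: np.ndarray  # (n_corpus, n_features) z-scored
    specimen_ids: list[str]
    reports: list[Report]

    def __len__(self) -> int:
        return len(self.specimen_ids)


def _raw_vector(panel: PanelResult, analyte_ids: Sequence[str]) -> np.ndarray:
    return np.asarray(
        [np.nan if panel.values[a] is None else panel.values[a] for a in analyte_ids],
        dtype=float,
    )


def fit_standardization(panels: Sequence[PanelResult], schema: PanelSchema) -> Standardization:
    """Per-analyte corpus mean and SD; a degenerate (zero-SD) feature falls
    back to scale 1 with a warning."""
    analyte_ids = schema.analyte_ids
    raw = np.vstack([_raw_vector(p, analyte_ids) for p in panels])
    center = np.nanmean(raw, axis=0)
    center = np.where(np.isnan(center), 0.0, center)
    scale = np.nanstd(raw, axis=0)
    scale = np.where(np.isnan(scale), 0.0, scale)
    if np.any(scale == 0):
        flat = [analyte_ids[i] for i in np.flatnonzero(scale == 0)]
        warnings.warn(
            f"zero variance for {flat}; using fallback scale 1", stacklevel=2
        )
        scale = np.where(scale == 0, 1.0, scale)
    return Standardization(list(analyte_ids), center, scale)


def vectorize_panel(
    panel: PanelResult,
    schema: PanelSchema,
    standardization: Standardization,
) -> tuple[np.ndarray, np.ndarray]:
    """Z-scored feature vector for a panel, plus a missing-value mask.

    Missing values are imputed to the corpus mean (z-score 0) and flagged.
    """
    if standardization.analyte_ids != schema.analyte_ids:
        raise SchemaError("standardization was fitted against a different schema")
    validate_panel(panel, schema)
    raw = _raw_vector(panel, standardization.analyte_ids)
    missing = np.isnan(raw)
    z = (raw - standardization.center) / standardization.scale
    z[missing] = 0.0
    return z, missing


def build_index(
    panels: Sequence[PanelResult],
    reports: Sequence[Report],
    schema: PanelSchema,
) -> RetrievalIndex:
    if len(panels) == 0:
        raise UsageError("cannot build a retrieval index from an empty corpus")
    if len(panels) != len(reports):
        raise UsageError(f"{len(panels)} panels vs {len(reports)} reports")
    for p, r in zip(panels, reports):
        if p.specimen_id != r.specimen_id:
            raise UsageError(f"panel/report mismatch: {p.specimen_id} vs {r.specimen_id}")
    standardization = fit_standardization(panels, schema)
    rows = [vectorize_panel(p, schema, standardization)[0] for p in panels]
    return RetrievalIndex(
        standardization=standardization,
        matrix=np.vstack(rows),
        specimen_ids=[p.specimen_id for p in panels],
        reports=list(reports),
    )


def _cosine_sims(matrix: np.ndarray, query: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=1)
    qnorm = np.linalg.norm(query)
    denom = norms * (qnorm if qnorm > 0 else 1.0)
    denom[denom == 0] = 1.0
    return matrix @ query / denom


def _best(sims: np.ndarray, candidates: Sequence[int]) -> int:
    """Earliest-index argmax over a candidate subset."""
    cand = np.asarray(candidates)
    sub = sims[cand]
    return int(cand[np.flatnonzero(sub == sub.max())[0]])


def retrieve_report(
    query: PanelResult,
    index: RetrievalIndex,
    granularity: str = "per_section",
) -> Report:
    """Predict a report for a query panel by nearest-neighbor lookup.

    ``whole_report`` returns the nearest corpus panel's report verbatim;
    ``per_section`` assembles each section from the nearest corpus panel
    among those whose report has that section.  Ties resolve to the
    earliest corpus index.  The returned report carries the query's
    specimen id; its comment metadata is not propagated (retrieved text is
    evaluated by extraction, like any externally generated report).
    """
    if len(index) == 0:
        raise UsageError("retrieval index is empty")
    if granularity not in ("whole_report", "per_section"):
        raise UsageError(f"unknown granularity: {granularity}")
    schema_ids = index.standardization.analyte_ids
    query_vec = np.asarray(
        [
            0.0 if query.values[a] is None else (query.values[a] - c) / s
            for a, c, s in zip(
                schema_ids, index.standardization.center, index.standardization.scale
            )
        ],
        dtype=float,
    )
    sims = _cosine_sims(index.matrix, query_vec)
    nearest = _best(sims, range(len(index)))
    if granularity == "whole_report":
        source = index.reports[nearest]
        sections = [ReportSection(s.label, list(s.sentences)) for s in source.sections]
        return Report(specimen_id=query.specimen_id, sections=sections)
    # Section layout follows the overall nearest neighbor (so an exact
    # corpus match reproduces its own report); each present section's text
    # comes from the nearest corpus panel that has that section.
    sections = []
    for label in SECTION_ORDER:
        if index.reports[nearest].section(label) is None:
            continue
        candidates = [
            i for i, r in enumerate(index.reports)
            if r.section(label) is not None and r.section(label).sentences
        ]
        best = _best(sims, candidates)
        src = index.reports[best].section(label)
        sections.append(ReportSection(label, list(src.sentences)))
    return Report(specimen_id=query.specimen_id, sections=sections)
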