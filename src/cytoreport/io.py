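"""Readers and writers for panels, reports, tuples, and metric tables.

Panels travel as CSV (one row per specimen, one column per analyte id)
or nested JSON; reports as plain text or JSON with section labels;
instruction-input-response tuples as JSONL; metrics as tidy CSV.  Units
metadata lives in the schema, never per row.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import SchemaError
from .evaluation import EvalRecord
from .panel import PanelResult, PanelSchema, validate_panel
from .reporting import Report, ReportSection, SectionLabel, TrainingTuple


# -- panels -----------------------------------------------------------------


def panels_to_frame(panels: Sequence[PanelResult], schema: PanelSchema) -> pd.DataFrame:
    rows = []
    for p in panels:
        validate_panel(p, schema)
        row = {"specimen_id": p.specimen_id, "patient_age": p.patient_age}
        row.update({a: p.values[a] for a in schema.analyte_ids})
        rows.append(row)
    return pd.DataFrame(rows, columns=["specimen_id", "patient_age", *schema.analyte_ids])


def write_panels_csv(path: str | Path, panels: Sequence[PanelResult], schema: PanelSchema) -> None:
    panels_to_frame(panels, schema).to_csv(path, index=False)


def read_panels_csv(path: str | Path, schema: PanelSchema) -> list[PanelResult]:
    df = pd.read_csv(path)
    required = {"specimen_id", "patient_age", *schema.analyte_ids}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    panels = []
    for _, row in df.iterrows():
        values = {
            a: (None if pd.isna(row[a]) else float(row[a])) for a in schema.analyte_ids
        }
        panels.append(
            PanelResult(
                specimen_id=str(row["specimen_id"]),
                patient_age=float(row["patient_age"]),
                values=values,
            )
        )
    return panels


def write_panels_json(path: str | Path, panels: Sequence[PanelResult], schema: PanelSchema) -> None:
    payload = []
    for p in panels:
        validate_panel(p, schema)
        payload.append(
            {"specimen_id": p.specimen_id, "patient_age": p.patient_age, "values": p.values}
        )
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_panels_json(path: str | Path, schema: PanelSchema) -> list[PanelResult]:
    payload = json.loads(Path(path).read_text())
    return [
        PanelResult(
            specimen_id=entry["specimen_id"],
            patient_age=float(entry["patient_age"]),
            values={k: (None if v is None else float(v)) for k, v in entry["values"].items()},
        )
        for entry in payload
    ]


# -- reports ----------------------------------------------------------------


def report_to_dict(report: Report) -> dict:
    return {
        "specimen_id": report.specimen_id,
        "sections": [
            {"label": s.label.value, "sentences": s.sentences} for s in report.sections
        ],
    }


def report_from_dict(payload: dict) -> Report:
    return Report(
        specimen_id=payload["specimen_id"],
        sections=[
            ReportSection(SectionLabel(s["label"]), list(s["sentences"]))
            for s in payload["sections"]
        ],
    )


def write_reports_json(path: str | Path, reports: Sequence[Report]) -> None:
    Path(path).write_text(
        json.dumps([report_to_dict(r) for r in reports], indent=1) + "\n"
    )


def read_reports_json(path: str | Path) -> list[Report]:
    return [report_from_dict(p) for p in json.loads(Path(path).read_text())]


def write_reports_text(path: str | Path, reports: Sequence[Report]) -> None:
    """Plain-text export: one block per report, blank-line separated."""
    blocks = [f"# {r.specimen_id}\n{r.text}" for r in reports]
    Path(path).write_text("\n\n".join(blocks) + "\n")


# -- training tuples --------------------------------------------------------


def write_training_tuples(path: str | Path, tuples: Iterable[TrainingTuple]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in tuples:
            fh.write(json.dumps(dataclasses.asdict(t)) + "\n")


def read_training_tuples(path: str | Path) -> list[TrainingTuple]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(TrainingTuple(**json.loads(line)))
    return out


# -- labeled sentence reference sets ----------------------------------------


def write_reference_csv(path: str | Path, labeled: Sequence[tuple[str, SectionLabel]]) -> None:
    pd.DataFrame(
        [{"text": t, "label": l.value} for t, l in labeled]
    ).to_csv(path, index=False)


def read_reference_csv(path: str | Path) -> list[tuple[str, SectionLabel]]:
    df = pd.read_csv(path)
    return [(str(r["text"]), SectionLabel(r["label"])) for _, r in df.iterrows()]


# -- metric export ----------------------------------------------------------


def records_to_frame(
    records: Sequence[EvalRecord], method: Optional[str] = None
) -> pd.DataFrame:
    """Tidy per-cell-type metric table: one row per
    (specimen, cell_type, quantifier, metric)."""
    rows = []
    for rec in records:
        for (family, quant), tally in rec.per_cell.items():
            base = {
                "specimen_id": rec.specimen_id,
                "standard": rec.standard.value,
                "cell_type": family,
                "quantifier": quant,
            }
            if method is not None:
                base["method"] = method
            for metric, value in (
                ("n_abnormal", tally.n_abnormal),
                ("n_commented", tally.n_commented),
                ("n_direction_correct", tally.n_direction_correct),
                ("n_degree_correct", tally.n_degree_correct),
                ("n_unsupported", tally.n_unsupported),
                ("n_omitted", tally.n_omitted),
            ):
                rows.append({**base, "metric": metric, "value": value})
    return pd.DataFrame(rows)


def manifest_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, default=str) + "\n")
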