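"""End-to-end pipeline: generate -> render -> degrade/retrieve -> label ->
extract -> evaluate -> compare, with a reproducibility manifest.

Three report sources are evaluated side by side on a held-out cohort:

* ``pathologist`` — the deterministic reference renderer itself;
* ``degraded`` — the reference reports passed through the corruption
  operator (a stand-in text generator with controlled error rates);
* ``retrieval`` — the nearest-neighbor baseline indexed on a separate
  training cohort.

All generated text goes through the same sentence-labeling and statement
extraction stages before evaluation under both reference standards, as a
single uniform code path.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .errors import ConfigError
from .evaluation import (
    EvalRecord,
    MethodComparison,
    ReferenceStandard,
    UNDEFINED,
    compare_methods,
    evaluate_report,
    pbmc_check,
    prevalence_correlation,
)
from .extraction import AliasDictionary, default_aliases, extract_statements
from .io import manifest_hash, records_to_frame, write_manifest, write_panels_csv
from .labeling import HashingEmbedder, ReferenceSet, build_reference, label_sentence
from .panel import PanelSchema, default_schema, load_schema
from .reporting import (
    CorruptionSpec,
    Report,
    SectionLabel,
    corrupt_report,
    get_style,
    render_report,
)
from .retrieval import build_index, retrieve_report
from .synthetic import CohortProfile, generate_cohort, table1_profile


class RunConfig(BaseModel):
    """Configuration of one pipeline run; the manifest hash of this object
    plus the seed fully determines every output."""

    schema_path: Optional[str] = None
    profile: Optional[CohortProfile] = None
    n_train: int = Field(default=300, gt=0)
    n_eval: int = Field(default=200, gt=0)
    style: str = "harmonized"
    corruption: CorruptionSpec = CorruptionSpec(
        omit_comment=0.15, flip_direction=0.05, shift_degree=0.05,
        swap_quantifier=0.05, hallucinate_statement=0.05,
    )
    knn_k: int = 5
    embedding_dim: int = 256
    retrieval_granularity: str = "per_section"
    seed: int = 0
    out_dir: Optional[str] = None


@dataclass
class PipelineResult:
    manifest: dict
    metrics: pd.DataFrame
    summary: dict
    records: dict[str, dict[str, list[EvalRecord]]]
    comparisons: dict[str, MethodComparison]


def _statements_via_labeler(
    report: Report,
    reference: ReferenceSet,
    aliases: AliasDictionary,
    k: int,
    backend: HashingEmbedder,
) -> list:
    """Label each sentence, then extract from QLP/BSP-labeled sentences."""
    statements = []
    for idx, _true_label, sentence in report.iter_sentences():
        label, _margin = label_sentence(sentence, reference, k=k, backend=backend)
        if label in (SectionLabel.QLP, SectionLabel.BSP):
            statements.extend(extract_statements(sentence, aliases, sentence_index=idx))
    return statements


def run_pipeline(config: RunConfig) -> PipelineResult:
    schema = load_schema(config.schema_path) if config.schema_path else default_schema()
    profile = config.profile or table1_profile()
    aliases = default_aliases()
    style = get_style(config.style)
    backend = HashingEmbedder(dim=config.embedding_dim)

    train_profile = profile.model_copy(
        update={"n": config.n_train, "seed": (config.seed * 2 + 1) % 2**31}
    )
    eval_profile = profile.model_copy(
        update={"n": config.n_eval, "seed": (config.seed * 2 + 2) % 2**31}
    )
    train_panels = generate_cohort(train_profile, schema)
    eval_panels = generate_cohort(eval_profile, schema)

    train_reports = [render_report(p, schema, style, aliases) for p in train_panels]
    eval_reports = [render_report(p, schema, style, aliases) for p in eval_panels]

    # Sentence-labeling reference set: renderer-labeled training sentences.
    labeled = [
        (sentence, label)
        for report in train_reports
        for _, label, sentence in report.iter_sentences()
    ]
    reference_set = build_reference(labeled, backend)

    index = build_index(train_panels, train_reports, schema)

    methods: dict[str, list[Report]] = {"pathologist": eval_reports}
    degraded = []
    for i, (panel, report) in enumerate(zip(eval_panels, eval_reports)):
        corrupted, _log = corrupt_report(
            report, panel, schema, config.corruption,
            seed=(config.seed * 100003 + i) % 2**31, style=style, aliases=aliases,
        )
        degraded.append(corrupted)
    methods["degraded"] = degraded
    methods["retrieval"] = [
        retrieve_report(p, index, granularity=config.retrieval_granularity)
        for p in eval_panels
    ]

    records: dict[str, dict[str, list[EvalRecord]]] = {}
    pbmc_outcomes: dict[str, dict[str, int]] = {}
    statements_by_method: dict[str, list] = {}
    for method, reports in methods.items():
        statements_by_method[method] = [
            _statements_via_labeler(r, reference_set, aliases, config.knn_k, backend)
            for r in reports
        ]
    reference_statements = statements_by_method["pathologist"]

    for method, reports in methods.items():
        records[method] = {"lab": [], "reference": []}
        outcomes: dict[str, int] = {}
        for panel, report, stmts, ref_stmts in zip(
            eval_panels, reports, statements_by_method[method], reference_statements
        ):
            records[method]["lab"].append(
                evaluate_report(stmts, panel, schema, ReferenceStandard.LAB_VALUES)
            )
            records[method]["reference"].append(
                evaluate_report(
                    stmts, panel, schema, ReferenceStandard.REFERENCE_REPORT,
                    reference_statements=ref_stmts,
                )
            )
            outcome = pbmc_check(report, panel, schema)
            outcomes[outcome.value] = outcomes.get(outcome.value, 0) + 1
        pbmc_outcomes[method] = outcomes

    # Per-cell-type comment rates (lab standard), aligned across methods.
    cell_keys = sorted(
        {
            key
            for recs in records.values()
            for rec in recs["lab"]
            for key in rec.per_cell
        }
    )
    rate_tables: dict[str, list[float]] = {}
    for method in methods:
        rates = []
        for key in cell_keys:
            abnormal = sum(
                r.per_cell.get(key).n_abnormal if key in r.per_cell else 0
                for r in records[method]["lab"]
            )
            commented = sum(
                r.per_cell.get(key).n_commented if key in r.per_cell else 0
                for r in records[method]["lab"]
            )
            rates.append(commented / abnormal if abnormal else np.nan)
        rate_tables[method] = rates
    usable = [
        i for i in range(len(cell_keys))
        if all(not np.isnan(rate_tables[m][i]) for m in methods)
    ]
    comparisons: dict[str, MethodComparison] = {}
    if len(usable) >= 3:
        aligned = {m: [rate_tables[m][i] for i in usable] for m in methods}
        comparisons["comment_rate"] = compare_methods(aligned, paired=True)

    # Prevalence vs (degraded-method) comment rate across cell types.
    prevalence_table = []
    for i, key in enumerate(cell_keys):
        abnormal = sum(
            r.per_cell[key].n_abnormal if key in r.per_cell else 0
            for r in records["degraded"]["lab"]
        )
        rate = rate_tables["degraded"][i]
        prevalence_table.append((abnormal, None if np.isnan(rate) else rate))
    correlation = prevalence_correlation(prevalence_table)

    frames = [
        records_to_frame(records[m]["lab"] + records[m]["reference"], method=m)
        for m in methods
    ]
    metrics = pd.concat(frames, ignore_index=True)

    def _pooled(method: str, standard: str) -> dict:
        recs = records[method][standard]
        abnormal = sum(r.n_abnormal for r in recs)
        commented = sum(r.n_commented for r in recs)
        unsupported = sum(r.n_unsupported for r in recs)
        total_statements = commented + unsupported
        return {
            "n_abnormal": abnormal,
            "n_commented": commented,
            "n_unsupported": unsupported,
            "n_omitted": sum(r.n_omitted for r in recs),
            "comment_rate": commented / abnormal if abnormal else UNDEFINED,
            "unsupported_error_rate": (
                round(100 * unsupported / total_statements, 1)
                if total_statements
                else UNDEFINED
            ),
        }

    summary = {
        "methods": {
            m: {std: _pooled(m, std) for std in ("lab", "reference")} for m in methods
        },
        "pbmc_outcomes": pbmc_outcomes,
        "prevalence_correlation": correlation.r,
        "comparisons": {
            name: {
                "friedman_statistic": c.friedman_statistic,
                "friedman_p": c.friedman_p,
                "pairwise": [
                    {
                        "method_a": t.method_a,
                        "method_b": t.method_b,
                        "statistic": t.statistic,
                        "p_raw": t.p_raw,
                        "p_adj": t.p_adj,
                    }
                    for t in c.pairwise
                ],
            }
            for name, c in comparisons.items()
        },
    }

    config_payload = json.loads(config.model_dump_json())
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": config_payload,
        "config_hash": manifest_hash(config_payload),
        "seeds": {
            "base": config.seed,
            "train_cohort": train_profile.seed,
            "eval_cohort": eval_profile.seed,
        },
        "n_train": config.n_train,
        "n_eval": config.n_eval,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_panels_csv(out / "train_panels.csv", train_panels, schema)
        write_panels_csv(out / "eval_panels.csv", eval_panels, schema)
        metrics.to_csv(out / "metrics.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str) + "\n")
        write_manifest(out / "manifest.json", manifest)

    return PipelineResult(
        manifest=manifest,
        metrics=metrics,
        summary=summary,
        records=records,
        comparisons=comparisons,
    )
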