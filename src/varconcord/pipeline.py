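"""End-to-end orchestration: match -> filter -> concordance -> classify.

A run reads the two variant tables, matches and filters pairs, builds the
3x3 cross-classification and concordance report, optionally classifies
per-variant evidence profiles, and writes everything plus a run manifest
(config snapshot, input digests, per-stage record counts, output paths).
Re-running on identical inputs and config reproduces identical digests
for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .acmg import render_report
from .concordance import (
    ConcordanceReport,
    ContingencyTable,
    build_contingency,
    overall_concordance,
    project_concordance,
    round_half_away,
)
from .evidence import classify_profile, load_profiles
from .io import ConfigError, read_clinvar_table, read_uniprot_table, write_rejects_report
from .matching import FilterResult, apply_study_filters, match_variants

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "RunManifest", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    tool_version: str
    config: dict
    input_digests: dict[str, str]
    stage_counts: dict[str, int]
    outputs: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_config(config: Union[str, Path, dict]) -> dict:
    if isinstance(config, dict):
        return dict(config)
    doc = yaml.safe_load(Path(config).read_text())
    if not isinstance(doc, dict):
        raise ConfigError("pipeline config must be a mapping")
    return doc


_DEFAULTS = {
    "uniprot_dialect": "humsavar-2017",
    "clinvar_dialect": "clinvar-submissions-2017",
    "required_stars": 2,
    "ba1_cutoff": 0.05,
    "pm2_cutoff": 1e-4,
}


def run_pipeline(
    config: Union[str, Path, dict], out_dir: Union[str, Path]
) -> RunManifest:
    """Execute the full comparison pipeline as configured.

    The config maps ``uniprot_table`` and ``clinvar_table`` to input
    paths, optionally ``evidence_profiles`` to a YAML profile file, and
    may override dialects and thresholds. Outputs (matched pairs,
    exclusion summary, cross-table, concordance report, classification
    table and reports, manifest) are written under ``out_dir``. Any stage
    error aborts the run before outputs are written.
    """
    cfg = {**_DEFAULTS, **_load_config(config)}
    for key in ("uniprot_table", "clinvar_table"):
        if key not in cfg:
            raise ConfigError(f"pipeline config lacks {key!r}")
        if not Path(cfg[key]).exists():
            raise ConfigError(f"{key} {cfg[key]!r} does not exist")

    # ---- stage: read ----
    try:
        uniprot = read_uniprot_table(cfg["uniprot_table"], cfg["uniprot_dialect"])
        clinvar = read_clinvar_table(cfg["clinvar_table"], cfg["clinvar_dialect"])
    except Exception as exc:
        raise PipelineError(f"stage 'read' failed: {exc}") from exc
    if not uniprot.records or not clinvar.records:
        raise PipelineError("stage 'read' failed: an input table yielded no records")

    # ---- stage: match + filter ----
    try:
        pairs = match_variants(uniprot.records, clinvar.records)
        filtered: FilterResult = apply_study_filters(
            pairs, required_stars=int(cfg["required_stars"])
        )
    except Exception as exc:
        raise PipelineError(f"stage 'match' failed: {exc}") from exc
    if not filtered.retained:
        raise PipelineError("stage 'match' failed: no pairs survive the study filters")

    # ---- stage: concordance ----
    try:
        table = build_contingency(filtered.retained)
        report = overall_concordance(table)
    except Exception as exc:
        raise PipelineError(f"stage 'concord' failed: {exc}") from exc

    # ---- stage: classify (optional) ----
    classifications = []
    if cfg.get("evidence_profiles"):
        try:
            for profile in load_profiles(cfg["evidence_profiles"]):
                result = classify_profile(profile)
                classifications.append((profile, result))
        except Exception as exc:
            raise PipelineError(f"stage 'classify' failed: {exc}") from exc

    # ---- stage: write (only after every computing stage succeeded) ----
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    outputs["matched_pairs"] = out / "matched_pairs.tsv"
    _write_pairs(filtered, outputs["matched_pairs"])
    outputs["exclusions"] = out / "exclusions.tsv"
    pd.DataFrame(
        [
            {"filter": outcome.value, "excluded": count}
            for outcome, count in filtered.excluded.items()
        ]
    ).to_csv(outputs["exclusions"], sep="\t", index=False)
    outputs["rejects"] = out / "rejects.tsv"
    write_rejects_report(uniprot.rejects + clinvar.rejects, outputs["rejects"])
    outputs["contingency"] = out / "contingency.tsv"
    table.to_dataframe().to_csv(outputs["contingency"], sep="\t")
    outputs["concordance"] = out / "concordance.json"
    outputs["concordance"].write_text(_report_json(table, report))
    if classifications:
        outputs["classifications"] = out / "classifications.tsv"
        pd.DataFrame(
            [
                {
                    "variant": p.variant,
                    "classification": r.classification.value,
                    "conflicting": r.conflicting,
                    "evidence": ";".join(a.code.value for a in r.evidence_used),
                }
                for p, r in classifications
            ]
        ).to_csv(outputs["classifications"], sep="\t", index=False)
        report_dir = out / "reports"
        report_dir.mkdir(exist_ok=True)
        for p, r in classifications:
            slug = "".join(c if c.isalnum() else "_" for c in p.variant)[:60]
            (report_dir / f"{slug}.txt").write_text(render_report(r))

    manifest = RunManifest(
        tool_version=__version__,
        config={k: str(v) for k, v in cfg.items()},
        input_digests={
            "uniprot_table": _sha256(cfg["uniprot_table"]),
            "clinvar_table": _sha256(cfg["clinvar_table"]),
        },
        stage_counts={
            "uniprot_records": len(uniprot.records),
            "uniprot_rejects": len(uniprot.rejects),
            "clinvar_records": len(clinvar.records),
            "clinvar_rejects": len(clinvar.rejects),
            "matched_pairs": len(pairs),
            "retained_pairs": len(filtered.retained),
            **{
                f"excluded_{o.value}": n for o, n in filtered.excluded.items()
            },
            "classified_profiles": len(classifications),
        },
        outputs={name: str(path) for name, path in outputs.items()},
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _write_pairs(filtered: FilterResult, path: Path) -> None:
    rows = []
    for pair in filtered.retained:
        rows.append(
            {
                "gene": pair.uniprot.identity.gene_symbol,
                "accession": pair.uniprot.identity.protein_accession,
                "change": pair.uniprot.change.format(),
                "condition": pair.clinvar.condition,
                "match_key": pair.match_key.value,
                "ambiguous": pair.ambiguous,
                "uniprot_class": pair.uniprot.uniprot_class.value,
                "clinvar_class": (
                    pair.clinvar.aggregate_class.value
                    if pair.clinvar.aggregate_class
                    else ""
                ),
                "review_stars": pair.clinvar.review_stars,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "gene", "accession", "change", "condition", "match_key",
            "ambiguous", "uniprot_class", "clinvar_class", "review_stars",
        ],
    ).to_csv(path, sep="\t", index=False)


def _report_json(table: ContingencyTable, report: ConcordanceReport) -> str:
    doc = {
        "n_total": report.n_total,
        "n_agree": report.n_agree,
        "overall_percent": report.overall,
        "overall_percent_rounded": round_half_away(report.overall),
        "per_category_percent": {
            b.value: p for b, p in report.per_category.items()
        },
        "per_category_percent_rounded": {
            b.value: round_half_away(p) for b, p in report.per_category.items()
        },
        "contingency": table.counts.tolist(),
    }
    return json.dumps(doc, indent=2, sort_keys=True)
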