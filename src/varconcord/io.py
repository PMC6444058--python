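"""Readers and writers for the two tab-separated variant-table dialects.

Both readers are config-driven column maps. Two presets ship with the
package: ``humsavar-2017`` for curated-resource tables (one row per
variant x disease with a 3-class interpretation) and
``clinvar-submissions-2017`` / ``clinvar-summary-2017`` for submission
repositories, either one row per submitter (grouped here into aggregate
records with a derived review-star status) or pre-aggregated rows that
already carry a review-status column.

Malformed rows are never silently dropped: each reader returns the parsed
records together with a rejects report, and every input row appears in
exactly one of the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .models import (
    AcmgClass,
    ClinVarAggregateRecord,
    ClinVarSubmission,
    DiseaseModel,
    Inheritance,
    ParseError,
    Source,
    UniProtClass,
    VariantIdentity,
    VariantRecord,
    parse_protein_change,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "Dialect",
    "UNIPROT_DIALECTS",
    "CLINVAR_DIALECTS",
    "RejectedRow",
    "UniProtReadResult",
    "ClinVarReadResult",
    "read_uniprot_table",
    "write_uniprot_table",
    "read_clinvar_table",
    "write_clinvar_table",
    "write_rejects_report",
    "compute_review_status",
    "parse_uniprot_class",
    "parse_acmg_class",
    "parse_inheritance",
]


class ConfigError(ValueError):
    """A dialect or pipeline configuration is unusable."""


# ---------------------------------------------------------------------------
# Classification label synonyms (case-insensitive)
# ---------------------------------------------------------------------------

_UNIPROT_SYNONYMS = {
    "disease": UniProtClass.DISEASE,
    "disease causing": UniProtClass.DISEASE,
    "ld/d": UniProtClass.DISEASE,
    "polymorphism": UniProtClass.POLYMORPHISM,
    "lb/b": UniProtClass.POLYMORPHISM,
    "unclassified": UniProtClass.UNCLASSIFIED,
    "us": UniProtClass.UNCLASSIFIED,
}

_ACMG_SYNONYMS = {
    "pathogenic": AcmgClass.PATHOGENIC,
    "p": AcmgClass.PATHOGENIC,
    "likely pathogenic": AcmgClass.LIKELY_PATHOGENIC,
    "likely_pathogenic": AcmgClass.LIKELY_PATHOGENIC,
    "lp": AcmgClass.LIKELY_PATHOGENIC,
    "uncertain significance": AcmgClass.VUS,
    "uncertain_significance": AcmgClass.VUS,
    "of uncertain significance": AcmgClass.VUS,
    "vus": AcmgClass.VUS,
    "us": AcmgClass.VUS,
    "likely benign": AcmgClass.LIKELY_BENIGN,
    "likely_benign": AcmgClass.LIKELY_BENIGN,
    "lb": AcmgClass.LIKELY_BENIGN,
    "benign": AcmgClass.BENIGN,
    "b": AcmgClass.BENIGN,
}

_INHERITANCE_SYNONYMS = {
    "autosomal_dominant": Inheritance.AUTOSOMAL_DOMINANT,
    "autosomal dominant": Inheritance.AUTOSOMAL_DOMINANT,
    "ad": Inheritance.AUTOSOMAL_DOMINANT,
    "dominant": Inheritance.AUTOSOMAL_DOMINANT,
    "autosomal_recessive": Inheritance.AUTOSOMAL_RECESSIVE,
    "autosomal recessive": Inheritance.AUTOSOMAL_RECESSIVE,
    "ar": Inheritance.AUTOSOMAL_RECESSIVE,
    "recessive": Inheritance.AUTOSOMAL_RECESSIVE,
    "x_linked": Inheritance.X_LINKED,
    "x-linked": Inheritance.X_LINKED,
    "xl": Inheritance.X_LINKED,
}

# ClinVar-style review status phrases mapped to star counts, for
# pre-aggregated tables that print the phrase rather than the number.
_REVIEW_STATUS_PHRASES = {
    "no assertion criteria provided": 0,
    "criteria provided, single submitter": 1,
    "criteria provided, multiple submitters, no conflicts": 2,
    "criteria provided, conflicting interpretations": 1,
    "reviewed by expert panel": 3,
    "practice guideline": 4,
}


def _lookup(table: dict, label: str, what: str):
    key = " ".join(str(label).strip().lower().split())
    try:
        return table[key]
    except KeyError:
        accepted = ", ".join(sorted(table))
        raise ParseError(
            f"unknown {what} label {label!r}; accepted labels: {accepted}"
        ) from None


def parse_uniprot_class(label: str) -> UniProtClass:
    return _lookup(_UNIPROT_SYNONYMS, label, "3-class interpretation")


def parse_acmg_class(label: str) -> AcmgClass:
    return _lookup(_ACMG_SYNONYMS, label, "clinical significance")


def parse_inheritance(label: str) -> Inheritance:
    return _lookup(_INHERITANCE_SYNONYMS, label, "inheritance mode")


# ---------------------------------------------------------------------------
# Dialects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dialect:
    """A column map from logical field names to file column headers.

    ``required`` lists the logical fields that must resolve to a present
    column; all other mapped fields are read when their column exists.
    """

    name: str
    columns: dict[str, str]
    required: tuple[str, ...]
    per_submission: bool = False

    def col(self, logical: str) -> str:
        return self.columns.get(logical, logical)

    def check(self, header: list[str]) -> None:
        missing = [self.col(f) for f in self.required if self.col(f) not in header]
        if missing:
            raise ConfigError(
                f"dialect {self.name!r}: mandatory column(s) "
                f"{missing} absent from header {header}"
            )


UNIPROT_DIALECTS: dict[str, Dialect] = {
    "humsavar-2017": Dialect(
        name="humsavar-2017",
        columns={
            "gene": "gene_name",
            "accession": "swissprot_ac",
            "change": "aa_change",
            "uniprot_class": "variant_category",
            "rsid": "dbsnp",
            "hgvs_c": "hgvs_c",
            "disease": "disease_name",
            "omim": "omim_id",
            "inheritance": "inheritance",
            "mendelian": "mendelian",
            "prevalence": "prevalence",
            "penetrance": "penetrance",
            "carrier_frequency": "carrier_frequency",
        },
        required=("gene", "accession", "change", "uniprot_class", "disease"),
    ),
}

CLINVAR_DIALECTS: dict[str, Dialect] = {
    "clinvar-submissions-2017": Dialect(
        name="clinvar-submissions-2017",
        columns={
            "gene": "gene_symbol",
            "accession": "protein_accession",
            "rsid": "rsid",
            "hgvs_c": "hgvs_c",
            "hgvs_p": "hgvs_p",
            "condition": "condition",
            "submitter": "submitter",
            "classification": "clinical_significance",
            "criteria": "assertion_criteria",
            "expert_panel": "expert_panel",
            "practice_guideline": "practice_guideline",
        },
        required=("gene", "accession", "condition", "submitter", "classification"),
        per_submission=True,
    ),
    "clinvar-summary-2017": Dialect(
        name="clinvar-summary-2017",
        columns={
            "gene": "gene_symbol",
            "accession": "protein_accession",
            "rsid": "rsid",
            "hgvs_c": "hgvs_c",
            "hgvs_p": "hgvs_p",
            "condition": "condition",
            "classification": "clinical_significance",
            "review_status": "review_status",
        },
        required=("gene", "accession", "condition", "classification", "review_status"),
        per_submission=False,
    ),
}


def _resolve_dialect(dialect, presets: dict[str, Dialect]) -> Dialect:
    if isinstance(dialect, Dialect):
        return dialect
    try:
        return presets[dialect]
    except KeyError:
        raise ConfigError(
            f"unknown dialect {dialect!r}; shipped presets: {sorted(presets)}"
        ) from None


# ---------------------------------------------------------------------------
# Read results and rejects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RejectedRow:
    row_number: int  # 1-based data-row index (header excluded)
    reason: str
    raw: dict


@dataclass
class UniProtReadResult:
    records: list[VariantRecord]
    rejects: list[RejectedRow]


@dataclass
class ClinVarReadResult:
    records: list[ClinVarAggregateRecord]
    rejects: list[RejectedRow]


def write_rejects_report(rejects: list[RejectedRow], path: Union[str, Path]) -> None:
    """Write a tab-separated rejects report with a reason column."""
    rows = [
        {"row_number": r.row_number, "reason": r.reason, **r.raw} for r in rejects
    ]
    df = pd.DataFrame(rows, columns=None if rows else ["row_number", "reason"])
    df.to_csv(path, sep="\t", index=False)


def _cell(row: pd.Series, column: str) -> Optional[str]:
    if column not in row.index:
        return None
    value = row[column]
    if pd.isna(value) or str(value).strip() == "":
        return None
    return str(value).strip()


def _bool_cell(row: pd.Series, column: str, default: bool = False) -> bool:
    value = _cell(row, column)
    if value is None:
        return default
    return value.lower() in ("1", "true", "yes", "y")


def _float_cell(row: pd.Series, column: str) -> Optional[float]:
    value = _cell(row, column)
    return None if value is None else float(value)


def _read_tsv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# Curated-resource (humsavar-style) tables
# ---------------------------------------------------------------------------


def _disease_from_row(row: pd.Series, d: Dialect) -> DiseaseModel:
    inheritance_label = _cell(row, d.col("inheritance"))
    inheritance = (
        parse_inheritance(inheritance_label)
        if inheritance_label is not None
        else Inheritance.AUTOSOMAL_DOMINANT
    )
    penetrance = _float_cell(row, d.col("penetrance"))
    if penetrance is None:
        penetrance = 1.0
        logger.debug(
            "no penetrance for disease %r; assuming full penetrance",
            _cell(row, d.col("disease")),
        )
    return DiseaseModel(
        name=_cell(row, d.col("disease")) or "",
        omim_id=_cell(row, d.col("omim")),
        inheritance=inheritance,
        prevalence=_float_cell(row, d.col("prevalence")),
        penetrance=penetrance,
        carrier_frequency=_float_cell(row, d.col("carrier_frequency")),
        is_mendelian=_bool_cell(row, d.col("mendelian"), default=True),
    )


def read_uniprot_table(
    path: Union[str, Path], dialect: Union[str, Dialect] = "humsavar-2017"
) -> UniProtReadResult:
    """Read a curated-resource variant table.

    Returns the parsed records together with a rejects report; rows that
    fail to parse (bad protein-change token, unknown class label, no usable
    identity key) land in the rejects with the reason, never dropped.
    Rows whose disease is flagged non-Mendelian are retained but marked
    (``disease.is_mendelian``); the study filters exclude them later.
    """
    d = _resolve_dialect(dialect, UNIPROT_DIALECTS)
    df = _read_tsv(path)
    d.check(list(df.columns))
    records: list[VariantRecord] = []
    rejects: list[RejectedRow] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            change = parse_protein_change(_cell(row, d.col("change")) or "")
            identity = VariantIdentity(
                gene_symbol=_cell(row, d.col("gene")) or "",
                protein_accession=_cell(row, d.col("accession")) or "",
                rsid=_cell(row, d.col("rsid")),
                hgvs_c=_cell(row, d.col("hgvs_c")),
                hgvs_p=change.format(),
            )
            records.append(
                VariantRecord(
                    identity=identity,
                    change=change,
                    disease=_disease_from_row(row, d),
                    source=Source.UNIPROT,
                    uniprot_class=parse_uniprot_class(
                        _cell(row, d.col("uniprot_class")) or ""
                    ),
                )
            )
        except (ParseError, ValueError) as exc:
            rejects.append(RejectedRow(i, str(exc), row.to_dict()))
    return UniProtReadResult(records, rejects)


def write_uniprot_table(
    records: list[VariantRecord],
    path: Union[str, Path],
    dialect: Union[str, Dialect] = "humsavar-2017",
) -> None:
    d = _resolve_dialect(dialect, UNIPROT_DIALECTS)
    rows = []
    for r in records:
        dis = r.disease
        rows.append(
            {
                d.col("gene"): r.identity.gene_symbol,
                d.col("accession"): r.identity.protein_accession,
                d.col("change"): r.change.format(),
                d.col("uniprot_class"): r.uniprot_class.value,
                d.col("rsid"): r.identity.rsid or "",
                d.col("hgvs_c"): r.identity.hgvs_c or "",
                d.col("disease"): dis.name,
                d.col("omim"): dis.omim_id or "",
                d.col("inheritance"): dis.inheritance.value,
                d.col("mendelian"): str(dis.is_mendelian).lower(),
                d.col("prevalence"): "" if dis.prevalence is None else repr(dis.prevalence),
                d.col("penetrance"): repr(dis.penetrance),
                d.col("carrier_frequency"): ""
                if dis.carrier_frequency is None
                else repr(dis.carrier_frequency),
            }
        )
    pd.DataFrame(rows, columns=[d.col(f) for f in d.columns]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Review-star status
# ---------------------------------------------------------------------------


def compute_review_status(record: ClinVarAggregateRecord) -> int:
    """Derive the 0-4 review-star status of an aggregate record.

    4 stars: practice-guideline group; 3: expert panel; 2: at least two
    submitters with assertion criteria whose interpretations agree at the
    coarse bucket level (pathogenic-side / benign-side / uncertain, so P
    with LP still counts as concordant); 1: at least one submitter with
    criteria; 0 otherwise. Order-invariant in the submission list.
    """
    from .concordance import harmonize_class  # local import avoids a cycle

    if record.practice_guideline:
        return 4
    if record.expert_panel:
        return 3
    with_criteria = [s for s in record.submissions if s.assertion_criteria_provided]
    if len(with_criteria) >= 2:
        buckets = {harmonize_class(s.classification) for s in with_criteria}
        if len(buckets) == 1:
            return 2
    if with_criteria:
        return 1
    return 0


def _aggregate_class(record: ClinVarAggregateRecord) -> Optional[AcmgClass]:
    """Collapse submissions to one 5-tier label, or None on bucket conflict.

    Submissions with assertion criteria take precedence; all submissions
    are used when none provide criteria. Within an agreeing bucket a mix
    of confidence levels (P with LP) aggregates to the less confident
    member, mirroring how repositories display such records.
    """
    from .concordance import harmonize_class

    if not record.submissions:
        return None
    pool = [s for s in record.submissions if s.assertion_criteria_provided]
    if not pool:
        pool = list(record.submissions)
    buckets = {harmonize_class(s.classification) for s in pool}
    if len(buckets) > 1:
        return None
    labels = {s.classification for s in pool}
    if len(labels) == 1:
        return next(iter(labels))
    if AcmgClass.LIKELY_PATHOGENIC in labels:
        return AcmgClass.LIKELY_PATHOGENIC
    if AcmgClass.LIKELY_BENIGN in labels:
        return AcmgClass.LIKELY_BENIGN
    return next(iter(labels))


# ---------------------------------------------------------------------------
# Submission-repository (ClinVar-style) tables
# ---------------------------------------------------------------------------


def _parse_review_status(value: str) -> int:
    v = value.strip().lower()
    if v in _REVIEW_STATUS_PHRASES:
        return _REVIEW_STATUS_PHRASES[v]
    try:
        stars = int(v)
    except ValueError:
        accepted = sorted(_REVIEW_STATUS_PHRASES) + ["0-4"]
        raise ParseError(
            f"unknown review status {value!r}; accepted: {accepted}"
        ) from None
    if stars not in (0, 1, 2, 3, 4):
        raise ParseError(f"review status stars must be 0-4, got {stars}")
    return stars


def read_clinvar_table(
    path: Union[str, Path],
    dialect: Union[str, Dialect] = "clinvar-submissions-2017",
) -> ClinVarReadResult:
    """Read a submission-repository table into aggregate records.

    With a per-submission dialect, rows are grouped by variant identity and
    condition and the review-star status is computed from the submissions.
    With a pre-aggregated dialect each row is one record and the
    review-status column (star integer or status phrase) is parsed as-is.
    """
    d = _resolve_dialect(dialect, CLINVAR_DIALECTS)
    df = _read_tsv(path)
    if df.empty and list(df.columns):
        d.check(list(df.columns))
        return ClinVarReadResult([], [])
    if not df.empty:
        d.check(list(df.columns))
    rejects: list[RejectedRow] = []
    if not d.per_submission:
        records = []
        for i, (_, row) in enumerate(df.iterrows(), start=1):
            try:
                records.append(_aggregated_row_to_record(row, d))
            except (ParseError, ValueError) as exc:
                rejects.append(RejectedRow(i, str(exc), row.to_dict()))
        return ClinVarReadResult(records, rejects)

    groups: dict[tuple, ClinVarAggregateRecord] = {}
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            identity = VariantIdentity(
                gene_symbol=_cell(row, d.col("gene")) or "",
                protein_accession=_cell(row, d.col("accession")) or "",
                rsid=_cell(row, d.col("rsid")),
                hgvs_c=_cell(row, d.col("hgvs_c")),
                hgvs_p=_cell(row, d.col("hgvs_p")),
            )
            condition = _cell(row, d.col("condition")) or ""
            submission = ClinVarSubmission(
                submitter=_cell(row, d.col("submitter")) or "",
                classification=parse_acmg_class(
                    _cell(row, d.col("classification")) or ""
                ),
                assertion_criteria_provided=_bool_cell(row, d.col("criteria")),
                condition=condition,
            )
            key = (identity, condition)
            record = groups.get(key)
            if record is None:
                record = ClinVarAggregateRecord(identity=identity, condition=condition)
                groups[key] = record
            record.submissions.append(submission)
            record.expert_panel |= _bool_cell(row, d.col("expert_panel"))
            record.practice_guideline |= _bool_cell(row, d.col("practice_guideline"))
        except (ParseError, ValueError) as exc:
            rejects.append(RejectedRow(i, str(exc), row.to_dict()))
    records = list(groups.values())
    for record in records:
        record.review_stars = compute_review_status(record)
        record.aggregate_class = _aggregate_class(record)
    return ClinVarReadResult(records, rejects)


def _aggregated_row_to_record(row: pd.Series, d: Dialect) -> ClinVarAggregateRecord:
    identity = VariantIdentity(
        gene_symbol=_cell(row, d.col("gene")) or "",
        protein_accession=_cell(row, d.col("accession")) or "",
        rsid=_cell(row, d.col("rsid")),
        hgvs_c=_cell(row, d.col("hgvs_c")),
        hgvs_p=_cell(row, d.col("hgvs_p")),
    )
    stars = _parse_review_status(_cell(row, d.col("review_status")) or "")
    classification = parse_acmg_class(_cell(row, d.col("classification")) or "")
    record = ClinVarAggregateRecord(
        identity=identity,
        condition=_cell(row, d.col("condition")) or "",
        submissions=[],
        expert_panel=stars == 3,
        practice_guideline=stars == 4,
        review_stars=stars,
        aggregate_class=classification,
    )
    return record


def write_clinvar_table(
    records: list[ClinVarAggregateRecord],
    path: Union[str, Path],
    dialect: Union[str, Dialect] = "clinvar-submissions-2017",
) -> None:
    d = _resolve_dialect(dialect, CLINVAR_DIALECTS)
    rows = []
    for r in records:
        base = {
            d.col("gene"): r.identity.gene_symbol,
            d.col("accession"): r.identity.protein_accession,
            d.col("rsid"): r.identity.rsid or "",
            d.col("hgvs_c"): r.identity.hgvs_c or "",
            d.col("hgvs_p"): r.identity.hgvs_p or "",
            d.col("condition"): r.condition,
        }
        if d.per_submission:
            for s in r.submissions:
                rows.append(
                    {
                        **base,
                        d.col("submitter"): s.submitter,
                        d.col("classification"): s.classification.value,
                        d.col("criteria"): str(s.assertion_criteria_provided).lower(),
                        d.col("expert_panel"): str(r.expert_panel).lower(),
                        d.col("practice_guideline"): str(r.practice_guideline).lower(),
                    }
                )
        else:
            rows.append(
                {
                    **base,
                    d.col("classification"): (
                        r.aggregate_class.value if r.aggregate_class else ""
                    ),
                    d.col("review_status"): str(r.review_stars),
                }
            )
    pd.DataFrame(rows, columns=[d.col(f) for f in d.columns]).to_csv(
        path, sep="\t", index=False
    )
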