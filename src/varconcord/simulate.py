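"""Synthetic paired variant tables with known ground truth.

The generator emulates the statistical structure of a curated-resource /
submission-repository comparison: each synthetic variant receives a
latent curated bucket from a 3-class mixture, agrees with the repository
with a configurable probability (the concordance target), and — when
discordant — draws its repository bucket from a row-stochastic discord
kernel whose default is proportional to the off-diagonal structure of the
published 4286-variant comparison. Submission lists are fabricated to
realize a drawn review-star level, and evidence profiles are drawn from
per-class template libraries designed so the combining engine recovers
the latent bucket for template-pure profiles.

All randomness flows from a single integer seed; a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .evidence import (
    AssayEffect,
    EvidenceProfile,
    FunctionalAssay,
    PopulationObservation,
    PredictorVerdict,
    PredictorVerdicts,
)
from .acmg import EvidenceAssignment, EvidenceCode
from .io import (
    _aggregate_class,
    compute_review_status,
    write_clinvar_table,
    write_uniprot_table,
)
from .models import (
    AcmgClass,
    ClinVarAggregateRecord,
    ClinVarSubmission,
    DiseaseModel,
    Inheritance,
    ProteinChange,
    Source,
    UniProtClass,
    VariantIdentity,
    VariantRecord,
)

__all__ = ["GeneratorConfig", "SyntheticTables", "generate_paired_tables",
           "generate_evidence_profiles", "DEFAULT_TEMPLATES"]

_BUCKETS = (
    UniProtClass.DISEASE,
    UniProtClass.POLYMORPHISM,
    UniProtClass.UNCLASSIFIED,
)

_BUCKET_LABELS = {
    UniProtClass.DISEASE: (AcmgClass.PATHOGENIC, AcmgClass.LIKELY_PATHOGENIC),
    UniProtClass.POLYMORPHISM: (AcmgClass.BENIGN, AcmgClass.LIKELY_BENIGN),
    UniProtClass.UNCLASSIFIED: (AcmgClass.VUS,),
}

# Default discord kernel: rows proportional to the published comparison's
# off-diagonal counts ((111, 94), (46, 128), (55, 81)), diagonal zero.
_DEFAULT_KERNEL = np.array(
    [
        [0.0, 111 / 205, 94 / 205],
        [46 / 174, 0.0, 128 / 174],
        [55 / 136, 81 / 136, 0.0],
    ]
)

_AA = ("Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
       "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val")


def _check_simplex(vec, name: str, tol: float = 1e-9) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    if (v < 0).any() or abs(v.sum() - 1.0) > tol:
        raise ValueError(f"{name} must be non-negative and sum to 1, got {vec}")
    return v


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic comparison.

    Defaults mirror the published 4286-variant study: bucket mixture from
    its row marginals (1533 / 2502 / 251), overall concordance 0.88, and a
    discord kernel proportional to its off-diagonal counts. The star
    distribution describes the repository at large (most records have one
    or two criteria-backed submitters, few are panel-reviewed); the
    Mendelian fraction reflects that a small minority of curated disease
    associations are multifactorial.
    """

    seed: int = 0
    n_variants: int = 4286
    bucket_mixture: tuple[float, float, float] = (
        1533 / 4286,
        2502 / 4286,
        251 / 4286,
    )
    concordance_target: float = 0.88
    discord_kernel: np.ndarray = field(
        default_factory=lambda: _DEFAULT_KERNEL.copy()
    )
    star_distribution: tuple[float, ...] = (0.10, 0.45, 0.40, 0.04, 0.01)
    mendelian_fraction: float = 0.95
    evidence_profiles: Optional[dict[str, list[dict]]] = None

    def __post_init__(self) -> None:
        _check_simplex(self.bucket_mixture, "bucket_mixture")
        _check_simplex(self.star_distribution, "star_distribution")
        if not (0 <= self.concordance_target <= 1):
            raise ValueError("concordance_target must lie in [0, 1]")
        if not (0 <= self.mendelian_fraction <= 1):
            raise ValueError("mendelian_fraction must lie in [0, 1]")
        kernel = np.asarray(self.discord_kernel, dtype=float)
        if kernel.shape != (3, 3):
            raise ValueError("discord_kernel must be 3x3")
        for i in range(3):
            if kernel[i, i] != 0:
                raise ValueError("discord_kernel diagonal must be zero")
            _check_simplex(kernel[i], f"discord_kernel row {i}")
        self.discord_kernel = kernel


@dataclass
class SyntheticTables:
    """Generated record sets plus the latent truth table."""

    uniprot_records: list[VariantRecord]
    clinvar_records: list[ClinVarAggregateRecord]
    truth: pd.DataFrame

    def write(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "uniprot": out / "uniprot_variants.tsv",
            "clinvar": out / "clinvar_submissions.tsv",
            "truth": out / "truth.tsv",
        }
        write_uniprot_table(self.uniprot_records, paths["uniprot"])
        write_clinvar_table(self.clinvar_records, paths["clinvar"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _submissions_for_stars(
    stars: int, label: AcmgClass, rng: np.random.Generator, condition: str,
    bucket: UniProtClass,
) -> tuple[list[ClinVarSubmission], bool, bool]:
    """Fabricate a submission list realizing the drawn star level."""
    labels_in_bucket = _BUCKET_LABELS[bucket]
    if stars == 0:
        subs = [ClinVarSubmission("lab-1", label, False, condition)]
        return subs, False, False
    if stars == 1:
        subs = [ClinVarSubmission("lab-1", label, True, condition)]
        return subs, False, False
    if stars == 2:
        # two criteria-providing submitters, concordant at bucket level
        second = labels_in_bucket[int(rng.integers(len(labels_in_bucket)))]
        subs = [
            ClinVarSubmission("lab-1", label, True, condition),
            ClinVarSubmission("lab-2", second, True, condition),
        ]
        return subs, False, False
    subs = [ClinVarSubmission("expert-panel" if stars == 3 else "guideline-group",
                              label, True, condition)]
    return subs, stars == 3, stars == 4


def generate_paired_tables(cfg: GeneratorConfig) -> SyntheticTables:
    """Generate paired curated/repository tables with latent truth.

    Each variant draws a curated bucket from the mixture; with probability
    ``concordance_target`` the repository bucket matches (the 5-tier label
    drawn uniformly within the bucket), otherwise it comes from the
    discord kernel row. Identities are schematic (GENE00001, rs9xxxxxxxx)
    and shared between the two tables so the matcher can re-join them.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_variants
    mixture = np.asarray(cfg.bucket_mixture)
    u_idx = rng.choice(3, size=n, p=mixture)
    concordant = rng.random(n) < cfg.concordance_target
    c_idx = u_idx.copy()
    for i in np.nonzero(~concordant)[0]:
        c_idx[i] = rng.choice(3, p=cfg.discord_kernel[u_idx[i]])
    stars = rng.choice(5, size=n, p=np.asarray(cfg.star_distribution))
    mendelian = rng.random(n) < cfg.mendelian_fraction
    positions = rng.integers(2, 1000, size=n)
    ref_i = rng.integers(0, len(_AA), size=n)
    alt_shift = rng.integers(1, len(_AA), size=n)

    uniprot_records: list[VariantRecord] = []
    clinvar_records: list[ClinVarAggregateRecord] = []
    truth_rows = []
    for i in range(n):
        k = i + 1
        ref = _AA[ref_i[i]]
        alt = _AA[(ref_i[i] + alt_shift[i]) % len(_AA)]
        change = ProteinChange(ref, int(positions[i]), alt)
        condition = f"Synthetic disorder {k:05d}"
        identity = VariantIdentity(
            gene_symbol=f"GENE{k:05d}",
            protein_accession=f"X{k:06d}",
            rsid=f"rs9{k:08d}",
            hgvs_c=f"NM_9{k:06d}.1:c.{3 * int(positions[i])}A>G",
            hgvs_p=change.format(),
        )
        u_bucket = _BUCKETS[u_idx[i]]
        c_bucket = _BUCKETS[c_idx[i]]
        labels = _BUCKET_LABELS[c_bucket]
        label = labels[int(rng.integers(len(labels)))]
        disease = DiseaseModel(
            name=condition,
            inheritance=Inheritance.AUTOSOMAL_DOMINANT,
            is_mendelian=bool(mendelian[i]),
        )
        uniprot_records.append(
            VariantRecord(
                identity=identity,
                change=change,
                disease=disease,
                source=Source.UNIPROT,
                uniprot_class=u_bucket,
            )
        )
        subs, panel, guideline = _submissions_for_stars(
            int(stars[i]), label, rng, condition, c_bucket
        )
        record = ClinVarAggregateRecord(
            identity=identity,
            condition=condition,
            submissions=subs,
            expert_panel=panel,
            practice_guideline=guideline,
        )
        record.review_stars = compute_review_status(record)
        record.aggregate_class = _aggregate_class(record)
        clinvar_records.append(record)
        truth_rows.append(
            {
                "variant_id": f"GENE{k:05d}",
                "uniprot_bucket": u_bucket.value,
                "clinvar_bucket": c_bucket.value,
                "clinvar_label": label.value,
                "concordant": bool(concordant[i]),
                "review_stars": record.review_stars,
                "mendelian": bool(mendelian[i]),
            }
        )
    return SyntheticTables(uniprot_records, clinvar_records, pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# Evidence-profile templates
# ---------------------------------------------------------------------------

#: Per-bucket template library. Every template recovers its bucket under
#: the combining engine: pathogenic templates fire pathogenic-side rules,
#: benign templates benign-side rules, and unclassified templates fire
#: nothing (or conflict).
DEFAULT_TEMPLATES: dict[str, list[dict]] = {
    "disease": [
        {"supplied": ["PVS1", "PS1"]},
        {"supplied": ["PS1", "PM1", "PM2"]},
        {"supplied": ["PS3", "PM1"], "predictors": "deleterious"},
    ],
    "polymorphism": [
        {"frequency": 0.10},  # above the stand-alone cutoff -> BA1
        {"supplied": ["BS1", "BS2"]},
        {"supplied": ["BS1"], "predictors": "tolerated"},
    ],
    "unclassified": [
        {},  # no evidence -> uncertain
        {"supplied": ["PM2", "PM3", "BS3"]},  # conflicting evidence
    ],
}


def generate_evidence_profiles(
    cfg: GeneratorConfig, truth: pd.DataFrame
) -> list[EvidenceProfile]:
    """Draw an evidence profile per variant from its latent class's templates.

    Template purity guarantees the combining engine recovers the latent
    repository bucket: disease-latent variants classify pathogenic-side,
    polymorphism-latent benign-side, unclassified-latent as uncertain.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    templates = cfg.evidence_profiles or DEFAULT_TEMPLATES
    profiles: list[EvidenceProfile] = []
    for _, row in truth.iterrows():
        options = templates[row["clinvar_bucket"]]
        template = options[int(rng.integers(len(options)))]
        disease = DiseaseModel(
            name=f"Synthetic disorder for {row['variant_id']}",
            inheritance=Inheritance.AUTOSOMAL_DOMINANT,
            is_mendelian=bool(row["mendelian"]),
        )
        observations = []
        if "frequency" in template:
            observations.append(
                PopulationObservation(
                    dataset="synthetic-population",
                    allele_frequency=float(template["frequency"]),
                )
            )
        predictors = None
        if template.get("predictors") == "deleterious":
            predictors = PredictorVerdicts(
                PredictorVerdict.DELETERIOUS,
                PredictorVerdict.DELETERIOUS,
                PredictorVerdict.DELETERIOUS,
            )
        elif template.get("predictors") == "tolerated":
            predictors = PredictorVerdicts(
                PredictorVerdict.TOLERATED,
                PredictorVerdict.TOLERATED,
                PredictorVerdict.TOLERATED,
            )
        supplied = [
            EvidenceAssignment(
                EvidenceCode[code], justification="synthetic template evidence"
            )
            for code in template.get("supplied", [])
        ]
        profiles.append(
            EvidenceProfile(
                variant=str(row["variant_id"]),
                disease=disease,
                observations=observations,
                predictors=predictors,
                supplied=supplied,
            )
        )
    return profiles
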