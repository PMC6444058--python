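"""Derivation of ACMG evidence from population, computational and assay data.

The frequency logic rests on the maximum credible population allele
frequency: the highest allele frequency compatible with the variant
causing a disease of given prevalence, allelic heterogeneity, genotypic
contribution and penetrance,

    af_max = prevalence x allelic_heterogeneity x genotypic_contribution
             / penetrance .

An observed frequency above that threshold is strong benign evidence
(BS1); above the 5% population cutoff it is stand-alone (BA1); an
extremely low frequency with no homozygotes for a recessive disorder is
moderate pathogenic evidence (PM2). For recessive diseases with a known
carrier frequency, the comparison scale is the carrier allele frequency
(carrier frequency / 2) rather than the prevalence-derived product.

Computational predictions count only when all three predictors agree
(PP3 / BP4); functional assays count only when they reflect the disease
biology (PS3 / BS3). In-trans and segregation evidence (PM3, PP1, ...)
are literature-reported facts and enter as supplied assignments.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml

from .acmg import (
    ClassificationResult,
    EvidenceAssignment,
    EvidenceCode,
    Strength,
    adjust_strength,
    combine_evidence,
)
from .models import DiseaseModel, Inheritance

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdUnavailableError",
    "PopulationObservation",
    "PredictorVerdict",
    "PredictorVerdicts",
    "AssayEffect",
    "FunctionalAssay",
    "max_credible_af",
    "frequency_evidence",
    "computational_consensus",
    "functional_evidence",
    "EvidenceProfile",
    "derive_evidence",
    "classify_profile",
    "load_profiles",
    "dump_profiles",
]

#: Stand-alone benign cutoff on population allele frequency (BA1).
BA1_CUTOFF = 0.05
#: "Extremely low" frequency cutoff for PM2 in dominant disease.
PM2_CUTOFF_DOMINANT = 1e-4


class ThresholdUnavailableError(ValueError):
    """No frequency threshold can be derived (prevalence unknown)."""


@dataclass(frozen=True)
class PopulationObservation:
    """One population dataset's sighting of the variant."""

    dataset: str
    allele_frequency: float
    allele_count: Optional[int] = None
    homozygote_count: int = 0
    healthy_adult_observed: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.allele_frequency <= 1):
            raise ValueError("allele frequency must lie in [0, 1]")
        if self.allele_count is not None and self.homozygote_count > self.allele_count:
            raise ValueError("homozygote count cannot exceed allele count")


class PredictorVerdict(enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PredictorVerdicts:
    """Verdicts from the three sequence-based predictors."""

    polyphen: PredictorVerdict = PredictorVerdict.UNKNOWN
    sift: PredictorVerdict = PredictorVerdict.UNKNOWN
    mutation_taster: PredictorVerdict = PredictorVerdict.UNKNOWN


class AssayEffect(enum.Enum):
    DAMAGING = "damaging"
    NO_EFFECT = "no_effect"
    EQUIVOCAL = "equivocal"


@dataclass(frozen=True)
class FunctionalAssay:
    effect: AssayEffect
    reflects_biology: bool
    description: str = ""


def max_credible_af(
    d: DiseaseModel,
    allelic_heterogeneity: float = 1.0,
    genotypic_contribution: Optional[float] = None,
) -> float:
    """Maximum credible population allele frequency for a disease model.

    ``allelic_heterogeneity`` is the largest plausible share of cases
    attributable to this one allele; ``genotypic_contribution`` the share
    of the genotype's alleles this allele provides (default 1/2 for
    autosomal dominant — one of two alleles — and 1 otherwise). For
    recessive disorders the result sits on the carrier-allele scale only
    when prevalence is itself quadratic in allele frequency; when a
    carrier frequency is printed, prefer it directly (see
    :func:`frequency_evidence`).

    Raises :class:`ThresholdUnavailableError` when prevalence is unknown,
    in which case BS1 must not be fired.
    """
    if d.prevalence is None:
        raise ThresholdUnavailableError(
            f"no prevalence available for disease {d.name!r}"
        )
    if genotypic_contribution is None:
        genotypic_contribution = (
            0.5 if d.inheritance is Inheritance.AUTOSOMAL_DOMINANT else 1.0
        )
    if not (0 < allelic_heterogeneity <= 1):
        raise ValueError("allelic heterogeneity must lie in (0, 1]")
    if not (0 < genotypic_contribution <= 1):
        raise ValueError("genotypic contribution must lie in (0, 1]")
    return d.prevalence * allelic_heterogeneity * genotypic_contribution / d.penetrance


def _resolve_threshold(
    d: DiseaseModel, threshold: Optional[float]
) -> Optional[float]:
    if threshold is not None:
        return threshold
    if (
        d.inheritance is Inheritance.AUTOSOMAL_RECESSIVE
        and d.carrier_frequency is not None
    ):
        # carrier frequency counts heterozygous individuals; each carries
        # one variant allele out of two, hence the allele-scale factor 1/2
        return d.carrier_frequency / 2.0
    try:
        return max_credible_af(d)
    except ThresholdUnavailableError:
        logger.info(
            "no frequency threshold for %r: BS1 disabled, BA1/PM2 logic only",
            d.name,
        )
        return None


def frequency_evidence(
    obs: Sequence[PopulationObservation],
    d: DiseaseModel,
    threshold: Optional[float] = None,
    ba1_cutoff: float = BA1_CUTOFF,
    pm2_cutoff: float = PM2_CUTOFF_DOMINANT,
) -> list[EvidenceAssignment]:
    """Derive frequency-based evidence (BA1 / BS1 / PM2, plus BS2).

    The maximum observed frequency across datasets is compared against,
    in order: the 5% stand-alone cutoff (BA1), the disease-specific
    maximum credible frequency (BS1), and the extremely-low band (PM2 —
    for recessive disease the band is bounded by the carrier-scale
    threshold and additionally requires zero homozygotes). The bands are
    mutually exclusive, so BS1 and PM2 are never co-emitted. BS2 (observed
    in a healthy adult in the relevant genotype: homozygous for recessive,
    any carrier for dominant or X-linked) is independent of the bands.
    """
    if not obs:
        raise ValueError("at least one population observation is required")
    freq = max(o.allele_frequency for o in obs)
    top = max(obs, key=lambda o: o.allele_frequency)
    datasets = ", ".join(o.dataset for o in obs)
    resolved = _resolve_threshold(d, threshold)
    out: list[EvidenceAssignment] = []

    if freq > ba1_cutoff:
        out.append(
            EvidenceAssignment(
                EvidenceCode.BA1,
                justification=(
                    f"allele frequency {freq:g} in {top.dataset} exceeds the "
                    f"{ba1_cutoff:g} stand-alone cutoff"
                ),
                source=datasets,
            )
        )
    elif resolved is not None and freq > resolved:
        out.append(
            EvidenceAssignment(
                EvidenceCode.BS1,
                justification=(
                    f"allele frequency {freq:g} exceeds the maximum credible "
                    f"frequency {resolved:g} for {d.name}"
                ),
                source=datasets,
            )
        )
    else:
        total_homozygotes = sum(o.homozygote_count for o in obs)
        if d.inheritance is Inheritance.AUTOSOMAL_RECESSIVE:
            low = resolved if resolved is not None else pm2_cutoff
            if freq < low and total_homozygotes == 0:
                out.append(
                    EvidenceAssignment(
                        EvidenceCode.PM2,
                        justification=(
                            f"allele frequency {freq:g} is extremely low for a "
                            f"recessive disorder (below {low:g}) with no "
                            "homozygote reported"
                        ),
                        source=datasets,
                    )
                )
        elif freq < pm2_cutoff:
            out.append(
                EvidenceAssignment(
                    EvidenceCode.PM2,
                    justification=(
                        f"allele frequency {freq:g} below the extremely-low "
                        f"cutoff {pm2_cutoff:g}"
                    ),
                    source=datasets,
                )
            )

    healthy = [o for o in obs if o.healthy_adult_observed]
    if healthy:
        if d.inheritance is Inheritance.AUTOSOMAL_RECESSIVE:
            bs2_ok = any(o.homozygote_count > 0 for o in healthy)
        else:
            bs2_ok = True  # any healthy carrier for dominant / X-linked
        if bs2_ok:
            out.append(
                EvidenceAssignment(
                    EvidenceCode.BS2,
                    justification=(
                        "observed in healthy adult individual(s) in the "
                        f"genotype relevant for {d.inheritance.value} disease"
                    ),
                    source=", ".join(o.dataset for o in healthy),
                )
            )
    return out


def computational_consensus(v: PredictorVerdicts) -> Optional[EvidenceAssignment]:
    """Supporting evidence from predictor agreement.

    All three deleterious -> PP3; all three tolerated -> BP4; any
    disagreement or unknown verdict -> no evidence (predictions are used
    only when concordant).
    """
    verdicts = (v.polyphen, v.sift, v.mutation_taster)
    if all(x is PredictorVerdict.DELETERIOUS for x in verdicts):
        return EvidenceAssignment(
            EvidenceCode.PP3,
            justification="all three computational predictors call deleterious",
        )
    if all(x is PredictorVerdict.TOLERATED for x in verdicts):
        return EvidenceAssignment(
            EvidenceCode.BP4,
            justification="all three computational predictors call tolerated",
        )
    return None


def functional_evidence(
    assay_effect: AssayEffect, assay_reflects_biology: bool
) -> Optional[EvidenceAssignment]:
    """Strong functional evidence (PS3 / BS3) from a well-established assay.

    An assay that does not closely reflect the biological environment of
    the disease, or an equivocal result, contributes nothing (the finding
    is disregarded and logged rather than down-weighted).
    """
    if not assay_reflects_biology or assay_effect is AssayEffect.EQUIVOCAL:
        logger.info(
            "functional assay disregarded (effect=%s, reflects_biology=%s)",
            assay_effect.value,
            assay_reflects_biology,
        )
        return None
    if assay_effect is AssayEffect.DAMAGING:
        return EvidenceAssignment(
            EvidenceCode.PS3,
            justification="well-established functional assay shows a damaging effect",
        )
    return EvidenceAssignment(
        EvidenceCode.BS3,
        justification="well-established functional assay shows no damaging effect",
    )


# ---------------------------------------------------------------------------
# Evidence profiles: everything known about one variant, ready to classify
# ---------------------------------------------------------------------------


@dataclass
class EvidenceProfile:
    """Per-variant evidence inputs for re-classification.

    ``supplied`` holds literature-reported assignments the pipeline does
    not derive (PM3 in-trans observations, PP1 segregation, PS1/PM5 prior
    variants at the residue, ...). ``adjustments`` re-weights derived or
    supplied codes, each with its justification.
    """

    variant: str
    disease: DiseaseModel
    observations: list[PopulationObservation] = field(default_factory=list)
    predictors: Optional[PredictorVerdicts] = None
    assays: list[FunctionalAssay] = field(default_factory=list)
    supplied: list[EvidenceAssignment] = field(default_factory=list)
    adjustments: list[tuple[EvidenceCode, Strength, str]] = field(default_factory=list)
    threshold: Optional[float] = None


def derive_evidence(profile: EvidenceProfile) -> list[EvidenceAssignment]:
    """Turn a profile into concrete evidence assignments.

    Frequency, computational and functional evidence are derived; supplied
    assignments are appended; strength adjustments are then applied to
    whichever assignment carries the adjusted code.
    """
    out: list[EvidenceAssignment] = []
    if profile.observations:
        out.extend(
            frequency_evidence(
                profile.observations, profile.disease, threshold=profile.threshold
            )
        )
    if profile.predictors is not None:
        consensus = computational_consensus(profile.predictors)
        if consensus is not None:
            out.append(consensus)
    for assay in profile.assays:
        derived = functional_evidence(assay.effect, assay.reflects_biology)
        if derived is not None:
            out.append(derived)
    out.extend(profile.supplied)
    for code, new_strength, justification in profile.adjustments:
        for i, a in enumerate(out):
            if a.code is code:
                out[i] = adjust_strength(a, new_strength, justification)
                break
        else:
            logger.warning(
                "adjustment for %s ignored: code not present in derived evidence",
                code.value,
            )
    return out


def classify_profile(profile: EvidenceProfile) -> ClassificationResult:
    """Derive evidence from a profile and combine it into a 5-tier call."""
    return combine_evidence(derive_evidence(profile))


# ---------------------------------------------------------------------------
# Structured-text (YAML) profile IO
# ---------------------------------------------------------------------------


def _profile_to_dict(p: EvidenceProfile) -> dict:
    d = p.disease
    doc: dict = {
        "variant": p.variant,
        "disease": {
            "name": d.name,
            "inheritance": d.inheritance.value,
            "omim_id": d.omim_id,
            "prevalence": d.prevalence,
            "penetrance": d.penetrance,
            "carrier_frequency": d.carrier_frequency,
            "is_mendelian": d.is_mendelian,
        },
    }
    if p.observations:
        doc["observations"] = [
            {
                "dataset": o.dataset,
                "allele_frequency": o.allele_frequency,
                "allele_count": o.allele_count,
                "homozygote_count": o.homozygote_count,
                "healthy_adult_observed": o.healthy_adult_observed,
            }
            for o in p.observations
        ]
    if p.predictors is not None:
        doc["predictors"] = {
            "polyphen": p.predictors.polyphen.value,
            "sift": p.predictors.sift.value,
            "mutation_taster": p.predictors.mutation_taster.value,
        }
    if p.assays:
        doc["assays"] = [
            {
                "effect": a.effect.value,
                "reflects_biology": a.reflects_biology,
                "description": a.description,
            }
            for a in p.assays
        ]
    if p.supplied:
        doc["supplied"] = [
            {
                "code": a.code.value,
                "strength": a.applied_strength.name.lower(),
                "justification": a.justification,
                "source": a.source,
            }
            for a in p.supplied
        ]
    if p.adjustments:
        doc["adjustments"] = [
            {
                "code": code.value,
                "strength": strength.name.lower(),
                "justification": justification,
            }
            for code, strength, justification in p.adjustments
        ]
    if p.threshold is not None:
        doc["threshold"] = p.threshold
    return doc


def _profile_from_dict(doc: dict) -> EvidenceProfile:
    from .io import parse_inheritance  # synonym handling lives with IO

    d = doc["disease"]
    disease = DiseaseModel(
        name=d["name"],
        inheritance=parse_inheritance(d["inheritance"]),
        omim_id=d.get("omim_id"),
        prevalence=d.get("prevalence"),
        penetrance=d.get("penetrance") or 1.0,
        carrier_frequency=d.get("carrier_frequency"),
        is_mendelian=d.get("is_mendelian", True),
    )
    observations = [
        PopulationObservation(
            dataset=o["dataset"],
            allele_frequency=float(o["allele_frequency"]),
            allele_count=o.get("allele_count"),
            homozygote_count=int(o.get("homozygote_count", 0)),
            healthy_adult_observed=bool(o.get("healthy_adult_observed", False)),
        )
        for o in doc.get("observations", [])
    ]
    predictors = None
    if "predictors" in doc:
        p = doc["predictors"]
        predictors = PredictorVerdicts(
            polyphen=PredictorVerdict(p.get("polyphen", "unknown")),
            sift=PredictorVerdict(p.get("sift", "unknown")),
            mutation_taster=PredictorVerdict(p.get("mutation_taster", "unknown")),
        )
    assays = [
        FunctionalAssay(
            effect=AssayEffect(a["effect"]),
            reflects_biology=bool(a["reflects_biology"]),
            description=a.get("description", ""),
        )
        for a in doc.get("assays", [])
    ]
    supplied = [
        EvidenceAssignment(
            code=EvidenceCode[s["code"]],
            applied_strength=Strength[s["strength"].upper()] if "strength" in s else None,
            justification=s.get("justification", ""),
            source=s.get("source", ""),
        )
        for s in doc.get("supplied", [])
    ]
    adjustments = [
        (
            EvidenceCode[a["code"]],
            Strength[a["strength"].upper()],
            a["justification"],
        )
        for a in doc.get("adjustments", [])
    ]
    return EvidenceProfile(
        variant=doc["variant"],
        disease=disease,
        observations=observations,
        predictors=predictors,
        assays=assays,
        supplied=supplied,
        adjustments=adjustments,
        threshold=doc.get("threshold"),
    )


def load_profiles(path: Union[str, Path]) -> list[EvidenceProfile]:
    """Load evidence profiles from a YAML document (a list of profiles)."""
    docs = yaml.safe_load(Path(path).read_text())
    if docs is None:
        return []
    return [_profile_from_dict(doc) for doc in docs]


def dump_profiles(profiles: Sequence[EvidenceProfile], path: Union[str, Path]) -> None:
    """Write evidence profiles to YAML, round-trippable via load_profiles."""
    Path(path).write_text(
        yaml.safe_dump([_profile_to_dict(p) for p in profiles], sort_keys=False)
    )
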