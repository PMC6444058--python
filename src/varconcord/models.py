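"""Domain model for clinical variant interpretation records.

Two classification schemes coexist in this package. Expert-curated protein
resources label a variant x disease association as disease-causing,
polymorphism or unclassified (a 3-class scheme), while clinical submission
repositories use the ACMG-AMP 5-tier scheme (pathogenic, likely pathogenic,
uncertain significance, likely benign, benign). The types here carry both,
together with the identity keys (dbSNP rsID, transcript and protein HGVS
names) used to match variants across resources, and the disease model
(inheritance, prevalence, penetrance, carrier frequency) that drives
population-frequency evidence thresholds.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Optional

from Bio.Data.IUPACData import protein_letters_3to1_extended

__all__ = [
    "ParseError",
    "UniProtClass",
    "AcmgClass",
    "Inheritance",
    "Source",
    "ProteinChange",
    "parse_protein_change",
    "VariantIdentity",
    "DiseaseModel",
    "VariantRecord",
    "ClinVarSubmission",
    "ClinVarAggregateRecord",
]


class ParseError(ValueError):
    """A token or row could not be interpreted as valid input."""


class UniProtClass(enum.Enum):
    """3-class interpretation used by curated protein variant resources."""

    DISEASE = "disease"
    POLYMORPHISM = "polymorphism"
    UNCLASSIFIED = "unclassified"


class AcmgClass(enum.Enum):
    """5-tier clinical significance per the ACMG-AMP guideline."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely pathogenic"
    VUS = "uncertain significance"
    LIKELY_BENIGN = "likely benign"
    BENIGN = "benign"


class Inheritance(enum.Enum):
    AUTOSOMAL_DOMINANT = "autosomal_dominant"
    AUTOSOMAL_RECESSIVE = "autosomal_recessive"
    X_LINKED = "x_linked"


class Source(enum.Enum):
    UNIPROT = "uniprot"
    CLINVAR = "clinvar"


# Three-letter amino-acid codes (standard 20 plus extended codes such as
# Sec and Ter), title-cased as they appear in HGVS protein names.
_AA3 = {code.capitalize() for code in protein_letters_3to1_extended} | {"Ter"}

_PROTEIN_CHANGE_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")

_RSID_RE = re.compile(r"^rs[0-9]+$")


@dataclass(frozen=True)
class ProteinChange:
    """A single amino-acid substitution, e.g. Ile808Met.

    ``ref_aa`` and ``alt_aa`` are three-letter codes; ``position`` is the
    1-based residue number in the protein.
    """

    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa not in _AA3:
            raise ParseError(f"unknown amino-acid code {self.ref_aa!r}")
        if self.alt_aa not in _AA3:
            raise ParseError(f"unknown amino-acid code {self.alt_aa!r}")
        if self.position < 1:
            raise ParseError(f"residue position must be >= 1, got {self.position}")

    @property
    def is_missense(self) -> bool:
        """True for a substitution of one residue by a different residue."""
        return (
            self.ref_aa != self.alt_aa
            and self.ref_aa != "Ter"
            and self.alt_aa != "Ter"
        )

    def format(self) -> str:
        """Render back to the ``p.Ile808Met`` HGVS-style token."""
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


def parse_protein_change(token: str) -> ProteinChange:
    """Parse an HGVS-style protein substitution token such as ``p.Ile808Met``.

    Only missense substitutions are accepted: a token whose reference and
    alternate residues are identical (synonymous) is rejected, as are stop
    codons on either side.

    Raises
    ------
    ParseError
        If the token is malformed or does not describe a missense change.
        The message names the offending token.
    """
    m = _PROTEIN_CHANGE_RE.match(token.strip())
    if m is None:
        raise ParseError(f"cannot parse protein change token {token!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    try:
        change = ProteinChange(ref, pos, alt)
    except ParseError as exc:
        raise ParseError(f"bad protein change token {token!r}: {exc}") from None
    if not change.is_missense:
        raise ParseError(f"protein change {token!r} is not missense")
    return change


def normalize_rsid(rsid: str) -> str:
    """Normalize a dbSNP identifier to a lowercase ``rs`` prefix."""
    rsid = rsid.strip()
    if rsid[:2].lower() == "rs":
        rsid = "rs" + rsid[2:]
    return rsid


@dataclass(frozen=True)
class VariantIdentity:
    """Identity keys for one variant, used for cross-resource matching.

    At least one of rsid, hgvs_c, or (hgvs_p together with the protein
    accession) must be present so the variant can be matched at all.
    """

    gene_symbol: str
    protein_accession: str
    rsid: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rsid is not None:
            object.__setattr__(self, "rsid", normalize_rsid(self.rsid))
            if not _RSID_RE.match(self.rsid):
                raise ParseError(f"invalid dbSNP identifier {self.rsid!r}")
        if self.hgvs_c is not None:
            object.__setattr__(self, "hgvs_c", self.hgvs_c.strip())
        if self.hgvs_p is not None:
            object.__setattr__(self, "hgvs_p", self.hgvs_p.strip())
        has_protein_key = self.hgvs_p is not None and bool(self.protein_accession)
        if self.rsid is None and self.hgvs_c is None and not has_protein_key:
            raise ParseError(
                "variant identity needs an rsid, an hgvs_c, or an hgvs_p "
                f"with a protein accession (gene {self.gene_symbol!r})"
            )


@dataclass(frozen=True)
class DiseaseModel:
    """Disease parameters feeding allele-frequency evidence thresholds.

    prevalence, penetrance and carrier_frequency are fractions in (0, 1].
    Penetrance defaults to full (1.0); incomplete penetrance raises the
    maximum credible population allele frequency proportionally.
    ``is_mendelian`` is False for multifactorial disorders, which are
    excluded from ACMG-based comparison.
    """

    name: str
    inheritance: Inheritance
    omim_id: Optional[str] = None
    prevalence: Optional[float] = None
    penetrance: float = 1.0
    carrier_frequency: Optional[float] = None
    is_mendelian: bool = True

    def __post_init__(self) -> None:
        if self.prevalence is not None and not (0 < self.prevalence <= 1):
            raise ValueError(f"prevalence must lie in (0, 1], got {self.prevalence}")
        if not (0 < self.penetrance <= 1):
            raise ValueError(f"penetrance must lie in (0, 1], got {self.penetrance}")
        if self.carrier_frequency is not None and not (
            0 < self.carrier_frequency <= 1
        ):
            raise ValueError(
                f"carrier frequency must lie in (0, 1], got {self.carrier_frequency}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One variant x disease interpretation from one resource."""

    identity: VariantIdentity
    change: ProteinChange
    disease: DiseaseModel
    source: Source
    uniprot_class: Optional[UniProtClass] = None
    acmg_class: Optional[AcmgClass] = None

    def __post_init__(self) -> None:
        if self.source is Source.UNIPROT and self.uniprot_class is None:
            raise ValueError("a curated-resource record needs a 3-class interpretation")
        if self.source is Source.CLINVAR and self.acmg_class is None:
            raise ValueError("a submission-resource record needs a 5-tier class")


@dataclass(frozen=True)
class ClinVarSubmission:
    """One submitter's interpretation of a variant for one condition."""

    submitter: str
    classification: AcmgClass
    assertion_criteria_provided: bool = False
    condition: str = ""


@dataclass
class ClinVarAggregateRecord:
    """Grouped submissions for one variant x condition.

    ``review_stars`` summarizes submitter count, assertion criteria,
    concordance and expert review on ClinVar's 0-4 scale (see
    :func:`varconcord.io.compute_review_status`). ``aggregate_class`` is
    set only when the criteria-backed submissions agree at the coarse
    (pathogenic / benign / uncertain) bucket level.
    """

    identity: VariantIdentity
    condition: str
    submissions: list[ClinVarSubmission] = field(default_factory=list)
    expert_panel: bool = False
    practice_guideline: bool = False
    review_stars: int = 0
    aggregate_class: Optional[AcmgClass] = None

    def __post_init__(self) -> None:
        if self.review_stars not in (0, 1, 2, 3, 4):
            raise ValueError(f"review stars must be 0-4, got {self.review_stars}")


def _identity_key(identity: VariantIdentity) -> tuple:
    """A hashable canonical key for pairing records of the same variant."""
    return (
        identity.protein_accession,
        identity.rsid,
        identity.hgvs_c,
        identity.hgvs_p,
    )
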