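"""ACMG-AMP evidence model and combining rules.

An evidence code (PVS1, PS1-PS4, PM1-PM6, PP1-PP5 on the pathogenic side;
BA1, BS1-BS4, BP1-BP7 on the benign side) carries a polarity and a default
strength determined by its prefix. A curator may re-weight a code (with a
mandatory justification) but never flip its polarity. The combining rules
— shipped as data in ``data/acmg_rules.yaml`` so they are pinned
bit-exactly — count applied strengths per polarity and produce one of the
five tiers; when pathogenic-side and benign-side evidence cannot be
reconciled the result is uncertain significance with a conflict flag.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Iterable, Optional

import yaml

from .models import AcmgClass

__all__ = [
    "Polarity",
    "Strength",
    "EvidenceCode",
    "EvidenceAssignment",
    "ClassificationResult",
    "StrengthCounts",
    "adjust_strength",
    "combine_counts",
    "combine_evidence",
    "render_report",
    "parse_report_classification",
]


class Polarity(enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class Strength(enum.IntEnum):
    """Evidence strength, ordered weakest to strongest."""

    SUPPORTING = 1
    MODERATE = 2
    STRONG = 3
    VERY_STRONG = 4
    STAND_ALONE = 5


_CODE_FAMILIES = {
    "PVS": (Polarity.PATHOGENIC, Strength.VERY_STRONG),
    "PS": (Polarity.PATHOGENIC, Strength.STRONG),
    "PM": (Polarity.PATHOGENIC, Strength.MODERATE),
    "PP": (Polarity.PATHOGENIC, Strength.SUPPORTING),
    "BA": (Polarity.BENIGN, Strength.STAND_ALONE),
    "BS": (Polarity.BENIGN, Strength.STRONG),
    "BP": (Polarity.BENIGN, Strength.SUPPORTING),
}

_CODE_NAMES = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

EvidenceCode = enum.Enum("EvidenceCode", {name: name for name in _CODE_NAMES})
EvidenceCode.__doc__ = "The 28 named ACMG-AMP evidence criteria."


def _family(code: EvidenceCode) -> tuple[Polarity, Strength]:
    prefix = re.match(r"[A-Z]+", code.value).group(0)
    return _CODE_FAMILIES[prefix]


def code_polarity(code: EvidenceCode) -> Polarity:
    return _family(code)[0]


def code_default_strength(code: EvidenceCode) -> Strength:
    return _family(code)[1]


# attach as properties for ergonomic access
EvidenceCode.polarity = property(code_polarity)
EvidenceCode.default_strength = property(code_default_strength)


@dataclass(frozen=True)
class EvidenceAssignment:
    """One applied evidence criterion with provenance.

    ``applied_strength`` defaults to the code's guideline strength; it may
    only differ after :func:`adjust_strength`, which requires a
    justification. The default strength is always recoverable from the
    code for the report.
    """

    code: EvidenceCode
    applied_strength: Optional[Strength] = None
    justification: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.applied_strength is None:
            object.__setattr__(self, "applied_strength", self.code.default_strength)
        if (
            self.applied_strength != self.code.default_strength
            and not self.justification.strip()
        ):
            raise ValueError(
                f"{self.code.value}: re-weighting to "
                f"{self.applied_strength.name} requires a justification"
            )
        if (
            self.applied_strength is Strength.STAND_ALONE
            and self.code.polarity is not Polarity.BENIGN
        ):
            raise ValueError("stand-alone strength is reserved for benign evidence")

    @property
    def polarity(self) -> Polarity:
        return self.code.polarity

    @property
    def default_strength(self) -> Strength:
        return self.code.default_strength


def adjust_strength(
    a: EvidenceAssignment, new_strength: Strength, justification: str
) -> EvidenceAssignment:
    """Re-weight an evidence assignment, keeping polarity and provenance.

    The guideline lets a curator modify the default weighting of a
    criterion when circumstances warrant (e.g. treating BS2 as merely
    supporting for a disease with incomplete penetrance); the
    justification is mandatory and is carried into the report. Polarity is
    immutable: a benign code can never be applied as pathogenic evidence.
    """
    if not justification.strip():
        raise ValueError("a strength adjustment requires a non-empty justification")
    if not isinstance(new_strength, Strength):
        raise ValueError(f"unknown strength {new_strength!r}")
    if (
        new_strength is Strength.STAND_ALONE
        and a.code.polarity is not Polarity.BENIGN
    ):
        raise ValueError("cannot raise pathogenic evidence to stand-alone strength")
    return EvidenceAssignment(
        code=a.code,
        applied_strength=new_strength,
        justification=justification.strip(),
        source=a.source,
    )


@dataclass(frozen=True)
class StrengthCounts:
    """Counts of applied evidence strengths, split by polarity."""

    very_strong: int = 0
    strong: int = 0
    moderate: int = 0
    supporting: int = 0
    stand_alone: int = 0
    benign_strong: int = 0
    benign_supporting: int = 0

    @property
    def any_pathogenic(self) -> bool:
        return bool(
            self.very_strong or self.strong or self.moderate or self.supporting
        )

    @property
    def any_benign(self) -> bool:
        return bool(self.stand_alone or self.benign_strong or self.benign_supporting)


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of combining evidence: tier, fired rules, conflict flag.

    ``conflicting`` is True when the call is uncertain significance in the
    presence of evidence on both polarities — either because combining
    rules fired on both sides, or because the mixed evidence satisfies
    neither side. The classification is reproducible from
    ``evidence_used`` alone.
    """

    classification: AcmgClass
    fired_rules: tuple[str, ...]
    conflicting: bool
    evidence_used: tuple[EvidenceAssignment, ...]


@lru_cache(maxsize=1)
def _load_rules() -> dict[str, list[dict]]:
    text = resources.files("varconcord.data").joinpath("acmg_rules.yaml").read_text()
    return yaml.safe_load(text)


_BENIGN_KEY_MAP = {
    "stand_alone": "stand_alone",
    "strong": "benign_strong",
    "supporting": "benign_supporting",
}


def _fired(counts: StrengthCounts, outcome: str) -> list[str]:
    rules = _load_rules()[outcome]
    benign_side = outcome in ("benign", "likely_benign")
    fired = []
    for rule in rules:
        ok = True
        for strength_name, minimum in rule["requires"].items():
            attr = _BENIGN_KEY_MAP[strength_name] if benign_side else strength_name
            if getattr(counts, attr) < minimum:
                ok = False
                break
        if ok:
            fired.append(f"{outcome}: {rule['name']}")
    return fired


def combine_counts(counts: StrengthCounts) -> tuple[AcmgClass, tuple[str, ...], bool]:
    """Apply the combining-rule table to a strength-count vector.

    Returns (classification, fired rule names, conflicting). Pathogenic
    takes precedence over likely pathogenic on the pathogenic side, benign
    over likely benign on the benign side. Both sides firing, or neither
    side firing in the presence of mixed-polarity evidence, yields
    uncertain significance with the conflict flag set.
    """
    fired: list[str] = []
    path_call: Optional[AcmgClass] = None
    for outcome, tier in (
        ("pathogenic", AcmgClass.PATHOGENIC),
        ("likely_pathogenic", AcmgClass.LIKELY_PATHOGENIC),
    ):
        hits = _fired(counts, outcome)
        fired.extend(hits)
        if hits and path_call is None:
            path_call = tier
    benign_call: Optional[AcmgClass] = None
    for outcome, tier in (
        ("benign", AcmgClass.BENIGN),
        ("likely_benign", AcmgClass.LIKELY_BENIGN),
    ):
        hits = _fired(counts, outcome)
        fired.extend(hits)
        if hits and benign_call is None:
            benign_call = tier
    if path_call is not None and benign_call is not None:
        return AcmgClass.VUS, tuple(fired), True
    if path_call is not None:
        return path_call, tuple(fired), False
    if benign_call is not None:
        return benign_call, tuple(fired), False
    conflicting = counts.any_pathogenic and counts.any_benign
    return AcmgClass.VUS, tuple(fired), conflicting


def tally(evidence: Iterable[EvidenceAssignment]) -> StrengthCounts:
    """Count applied strengths per polarity, deduplicating by code."""
    seen: dict[EvidenceCode, EvidenceAssignment] = {}
    for a in evidence:
        seen.setdefault(a.code, a)
    kw = dict.fromkeys(
        (
            "very_strong",
            "strong",
            "moderate",
            "supporting",
            "stand_alone",
            "benign_strong",
            "benign_supporting",
        ),
        0,
    )
    for a in seen.values():
        if a.polarity is Polarity.PATHOGENIC:
            key = {
                Strength.VERY_STRONG: "very_strong",
                Strength.STRONG: "strong",
                Strength.MODERATE: "moderate",
                Strength.SUPPORTING: "supporting",
            }[a.applied_strength]
        else:
            key = {
                Strength.STAND_ALONE: "stand_alone",
                Strength.VERY_STRONG: "benign_strong",  # no benign very-strong bin
                Strength.STRONG: "benign_strong",
                Strength.MODERATE: "benign_supporting",
                Strength.SUPPORTING: "benign_supporting",
            }[a.applied_strength]
        kw[key] += 1
    return StrengthCounts(**kw)


def combine_evidence(evidence: Iterable[EvidenceAssignment]) -> ClassificationResult:
    """Combine evidence assignments into a 5-tier classification.

    Repeated identical codes are counted once (criteria are counted, not
    citations); the input order is irrelevant. An empty evidence list
    yields uncertain significance (no criteria met).
    """
    seen: dict[EvidenceCode, EvidenceAssignment] = {}
    for a in evidence:
        seen.setdefault(a.code, a)
    used = tuple(sorted(seen.values(), key=lambda a: a.code.value))
    classification, fired, conflicting = combine_counts(tally(used))
    return ClassificationResult(
        classification=classification,
        fired_rules=fired,
        conflicting=conflicting,
        evidence_used=used,
    )


_REPORT_CLASS_LINE = "Final classification: "


def render_report(r: ClassificationResult) -> str:
    """Render a deterministic plain-text interpretation report.

    Lists every evidence code with its default and applied strength,
    justification and source, the combining rules that fired, and the
    final classification. Byte-identical output for identical input.
    """
    lines = ["ACMG-AMP variant interpretation report", ""]
    if r.evidence_used:
        lines.append("Evidence:")
        for a in r.evidence_used:
            note = ""
            if a.applied_strength != a.default_strength:
                note = " (re-weighted)"
            lines.append(
                f"  {a.code.value}: default {a.default_strength.name.lower()}, "
                f"applied {a.applied_strength.name.lower()}{note}"
            )
            if a.justification:
                lines.append(f"    justification: {a.justification}")
            if a.source:
                lines.append(f"    source: {a.source}")
    else:
        lines.append("Evidence: none provided; no criteria met.")
    lines.append("")
    if r.fired_rules:
        lines.append("Combining rules fired:")
        lines.extend(f"  - {name}" for name in r.fired_rules)
    else:
        lines.append("Combining rules fired: none")
    if r.conflicting:
        lines.append("Conflicting evidence: pathogenic-side and benign-side "
                     "criteria cannot be reconciled.")
    lines.append("")
    lines.append(f"{_REPORT_CLASS_LINE}{_display_class(r.classification)}")
    return "\n".join(lines) + "\n"


def _display_class(c: AcmgClass) -> str:
    return c.value.capitalize()


def parse_report_classification(text: str) -> AcmgClass:
    """Recover the final classification from a rendered report."""
    for line in text.splitlines():
        if line.startswith(_REPORT_CLASS_LINE):
            return AcmgClass(line[len(_REPORT_CLASS_LINE):].strip().lower())
    raise ValueError("no final-classification line found in report")
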