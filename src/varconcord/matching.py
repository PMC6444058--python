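"""Cross-resource variant matching and study inclusion filters.

Variants are matched between the curated resource and the submission
repository on shared identifiers, with a fixed key precedence: dbSNP rsID
first, then the transcript-level HGVS name, then the protein-level HGVS
name qualified by the protein accession. Identifier comparison is exact
string equality after whitespace stripping (and a lowercase ``rs`` prefix
for rsIDs); versioned transcript names must match including the version.

The study filters then keep only pairs that are (a) missense, (b) backed
by a 2-star submission record (multiple criteria-providing submitters in
agreement) and (c) associated with a Mendelian disease. Each excluded
pair is attributed to exactly the first failing filter, in that order.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .models import ClinVarAggregateRecord, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MatchKey",
    "MatchedPair",
    "match_variants",
    "FilterOutcome",
    "FilterResult",
    "apply_study_filters",
]


class MatchKey(enum.Enum):
    RSID = "rsid"
    HGVS_C = "hgvs_c"
    HGVS_P = "hgvs_p"


@dataclass(frozen=True)
class MatchedPair:
    """One curated record paired with one aggregate submission record.

    ``ambiguous`` flags pairs whose shared key occurs on duplicate
    identities on either side; they are kept and logged, not dropped.
    """

    uniprot: VariantRecord
    clinvar: ClinVarAggregateRecord
    match_key: MatchKey
    ambiguous: bool = False


def _clinvar_keys(record: ClinVarAggregateRecord) -> dict[MatchKey, Optional[str]]:
    ident = record.identity
    hgvs_p = (
        f"{ident.protein_accession}:{ident.hgvs_p}" if ident.hgvs_p else None
    )
    return {
        MatchKey.RSID: ident.rsid,
        MatchKey.HGVS_C: ident.hgvs_c,
        MatchKey.HGVS_P: hgvs_p,
    }


def _uniprot_keys(record: VariantRecord) -> dict[MatchKey, Optional[str]]:
    ident = record.identity
    hgvs_p = ident.hgvs_p or record.change.format()
    return {
        MatchKey.RSID: ident.rsid,
        MatchKey.HGVS_C: ident.hgvs_c,
        MatchKey.HGVS_P: f"{ident.protein_accession}:{hgvs_p}",
    }


_PRECEDENCE = (MatchKey.RSID, MatchKey.HGVS_C, MatchKey.HGVS_P)


def match_variants(
    uniprot_set: Sequence[VariantRecord],
    clinvar_set: Sequence[ClinVarAggregateRecord],
) -> list[MatchedPair]:
    """Pair variants shared by the two resources on common identifiers.

    A curated variant matched through a higher-precedence key is not
    re-matched through a lower one. One pair is emitted per matching
    (curated variant x disease, submission variant x condition)
    combination. Output order is deterministic — sorted by gene symbol,
    residue position, then condition — and invariant under shuffling of
    either input.
    """
    indexes: dict[MatchKey, dict[str, list[ClinVarAggregateRecord]]] = {
        k: defaultdict(list) for k in _PRECEDENCE
    }
    for record in clinvar_set:
        for key_type, value in _clinvar_keys(record).items():
            if value is not None:
                indexes[key_type][value].append(record)

    duplicate_uniprot = _duplicate_key_values(
        _uniprot_keys(r) for r in uniprot_set
    )

    pairs: list[MatchedPair] = []
    for u in uniprot_set:
        keys = _uniprot_keys(u)
        for key_type in _PRECEDENCE:
            value = keys[key_type]
            if value is None:
                continue
            hits = indexes[key_type].get(value, [])
            if not hits:
                continue
            ambiguous = len(hits) > 1 or value in duplicate_uniprot
            if ambiguous:
                logger.warning(
                    "duplicate identity for %s key %r: all duplicates paired "
                    "and flagged ambiguous",
                    key_type.value,
                    value,
                )
            for c in hits:
                pairs.append(MatchedPair(u, c, key_type, ambiguous=ambiguous))
            break  # matched at this precedence; do not re-match lower
    pairs.sort(
        key=lambda p: (
            p.uniprot.identity.gene_symbol,
            p.uniprot.change.position,
            p.uniprot.change.alt_aa,
            p.uniprot.disease.name,
            p.clinvar.condition,
        )
    )
    return pairs


def _duplicate_key_values(key_maps: Iterable[dict[MatchKey, Optional[str]]]) -> set:
    seen: Counter = Counter()
    for keys in key_maps:
        for value in keys.values():
            if value is not None:
                seen[value] += 1
    return {v for v, n in seen.items() if n > 1}


class FilterOutcome(enum.Enum):
    RETAINED = "retained"
    NOT_MISSENSE = "not_missense"
    NOT_TWO_STAR = "not_two_star"
    NOT_MENDELIAN = "not_mendelian"


@dataclass
class FilterResult:
    """Retained pairs plus per-filter exclusion counts.

    Every input pair is attributed to exactly one outcome, so
    ``len(retained) + sum(excluded.values()) == n_input``.
    """

    retained: list[MatchedPair]
    excluded: dict[FilterOutcome, int]
    excluded_pairs: list[tuple[MatchedPair, FilterOutcome]]

    @property
    def n_input(self) -> int:
        return len(self.retained) + sum(self.excluded.values())


def apply_study_filters(
    pairs: Sequence[MatchedPair], required_stars: int = 2
) -> FilterResult:
    """Apply the study inclusion filters in the fixed order
    missense -> review stars -> Mendelian.

    Retains pairs where the protein change is missense, the submission
    record has exactly ``required_stars`` review stars (2 by default:
    multiple concordant criteria-providing submitters, no expert-panel
    validation), and the disease is Mendelian. Exclusions are attributed
    to the first failing filter only.
    """
    retained: list[MatchedPair] = []
    excluded: dict[FilterOutcome, int] = {
        FilterOutcome.NOT_MISSENSE: 0,
        FilterOutcome.NOT_TWO_STAR: 0,
        FilterOutcome.NOT_MENDELIAN: 0,
    }
    excluded_pairs: list[tuple[MatchedPair, FilterOutcome]] = []
    for pair in pairs:
        if not pair.uniprot.change.is_missense:
            outcome = FilterOutcome.NOT_MISSENSE
        elif pair.clinvar.review_stars != required_stars:
            outcome = FilterOutcome.NOT_TWO_STAR
        elif not pair.uniprot.disease.is_mendelian:
            outcome = FilterOutcome.NOT_MENDELIAN
        else:
            retained.append(pair)
            continue
        excluded[outcome] += 1
        excluded_pairs.append((pair, outcome))
    return FilterResult(retained, excluded, excluded_pairs)
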