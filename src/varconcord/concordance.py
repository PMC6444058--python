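"""Concordance statistics between 3-class and 5-tier interpretations.

The two classification schemes are compared at the level of three
harmonized buckets: disease-causing (pathogenic / likely pathogenic),
polymorphism (benign / likely benign) and unclassified (uncertain
significance). For one bucket, concordance is the number of
interpretations shared by both resources divided by the number of
interpretations in *either* resource (the union), times 100:

    concordance(b) = 100 * n_bb / (row_total(b) + col_total(b) - n_bb)

where n_bb is the diagonal cell of the 3x3 cross-classification. Overall
concordance is the trace over the grand total. Percentages are displayed
rounded to the nearest integer (half away from zero); the unrounded value
is always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import AcmgClass, UniProtClass, VariantRecord, _identity_key

__all__ = [
    "BUCKETS",
    "harmonize_class",
    "ContingencyTable",
    "ConcordanceReport",
    "build_contingency",
    "category_concordance",
    "overall_concordance",
    "build_transition",
    "project_concordance",
    "round_half_away",
    "UndefinedCategoryError",
]

#: Fixed bucket order used for all 3x3 tables (rows and columns).
BUCKETS: tuple[UniProtClass, ...] = (
    UniProtClass.DISEASE,
    UniProtClass.POLYMORPHISM,
    UniProtClass.UNCLASSIFIED,
)

_HARMONIZE = {
    AcmgClass.PATHOGENIC: UniProtClass.DISEASE,
    AcmgClass.LIKELY_PATHOGENIC: UniProtClass.DISEASE,
    AcmgClass.BENIGN: UniProtClass.POLYMORPHISM,
    AcmgClass.LIKELY_BENIGN: UniProtClass.POLYMORPHISM,
    AcmgClass.VUS: UniProtClass.UNCLASSIFIED,
}


class UndefinedCategoryError(ValueError):
    """Concordance is undefined for a bucket absent from both resources."""


def harmonize_class(c: AcmgClass) -> UniProtClass:
    """Map a 5-tier label onto the 3-class scheme.

    Pathogenic and likely pathogenic correspond to disease; benign and
    likely benign to polymorphism; uncertain significance to unclassified.
    """
    return _HARMONIZE[c]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (display rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ContingencyTable:
    """A 3x3 cross-classification of harmonized interpretations.

    Rows index the first resource's bucket (or the original bucket in a
    re-curation transition table), columns the second (or re-curated)
    bucket, both in :data:`BUCKETS` order. Diagonal cells are concordant
    interpretations.
    """

    counts: np.ndarray
    labels: tuple[UniProtClass, ...] = BUCKETS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} table, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("contingency cells must be non-negative")

    def _index(self, bucket: UniProtClass) -> int:
        return self.labels.index(bucket)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def row_total(self, bucket: UniProtClass) -> int:
        return int(self.counts[self._index(bucket), :].sum())

    def col_total(self, bucket: UniProtClass) -> int:
        return int(self.counts[:, self._index(bucket)].sum())

    def diagonal(self, bucket: UniProtClass) -> int:
        i = self._index(bucket)
        return int(self.counts[i, i])

    def to_dataframe(self) -> pd.DataFrame:
        names = [b.value for b in self.labels]
        return pd.DataFrame(self.counts, index=names, columns=names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ContingencyTable":
        labels = tuple(UniProtClass(name) for name in df.index)
        return cls(df.to_numpy(dtype=np.int64), labels)


@dataclass(frozen=True)
class ConcordanceReport:
    """Per-bucket and overall percent agreement for one comparison."""

    per_category: dict[UniProtClass, float]
    overall: float
    n_agree: int
    n_total: int

    def rounded(self) -> dict[str, int]:
        out = {b.value: round_half_away(p) for b, p in self.per_category.items()}
        out["overall"] = round_half_away(self.overall)
        return out


def build_contingency(pairs: Iterable) -> ContingencyTable:
    """Tally matched pairs into the 3x3 interpretation cross-table.

    Each pair contributes one count at (curated-resource bucket,
    harmonized submission-repository bucket). Every pair must carry both
    classifications; a missing one is an error naming the pair.
    """
    counts = np.zeros((3, 3), dtype=np.int64)
    index = {b: i for i, b in enumerate(BUCKETS)}
    for pair in pairs:
        u = pair.uniprot.uniprot_class
        c = pair.clinvar.aggregate_class
        if u is None or c is None:
            ident = pair.uniprot.identity
            raise ValueError(
                "pair missing a classification: "
                f"{ident.gene_symbol} {ident.protein_accession} "
                f"{pair.uniprot.change.format()} / {pair.clinvar.condition!r}"
            )
        counts[index[u], index[harmonize_class(c)]] += 1
    return ContingencyTable(counts)


def category_concordance(t: ContingencyTable, bucket: UniProtClass) -> float:
    """Percent concordance for one bucket with the union denominator.

    100 x diagonal / (row total + column total - diagonal). Undefined
    (raises) when the bucket is empty in both resources.
    """
    d = t.diagonal(bucket)
    union = t.row_total(bucket) + t.col_total(bucket) - d
    if union == 0:
        raise UndefinedCategoryError(
            f"concordance undefined: bucket {bucket.value!r} empty in both resources"
        )
    return 100.0 * d / union


def overall_concordance(t: ContingencyTable) -> ConcordanceReport:
    """Overall and per-bucket percent agreement for a cross-table.

    Overall agreement is 100 x trace / grand total; per-bucket values use
    the union denominator. Buckets empty in both resources are omitted
    from the per-category map.
    """
    if t.total == 0:
        raise ValueError("concordance undefined for an empty table")
    per_category: dict[UniProtClass, float] = {}
    for bucket in t.labels:
        try:
            per_category[bucket] = category_concordance(t, bucket)
        except UndefinedCategoryError:
            continue
    return ConcordanceReport(
        per_category=per_category,
        overall=100.0 * t.trace / t.total,
        n_agree=t.trace,
        n_total=t.total,
    )


def _bucket_of(record: VariantRecord) -> UniProtClass:
    if record.uniprot_class is not None:
        return record.uniprot_class
    if record.acmg_class is not None:
        return harmonize_class(record.acmg_class)
    raise ValueError("record carries no classification")


def build_transition(
    before: Sequence[VariantRecord], after: Sequence[VariantRecord]
) -> ContingencyTable:
    """Cross-tabulate original versus re-curated buckets.

    Records are paired by variant identity; the re-curated 5-tier label
    (when present) is harmonized to its bucket. Diagonal cells are
    interpretations confirmed by re-curation, off-diagonals modified ones.
    An identity present on one side only is an error.
    """
    after_by_key = {_identity_key(r.identity): r for r in after}
    if len(after_by_key) != len(after):
        raise ValueError("duplicate identities in the re-curated record set")
    counts = np.zeros((3, 3), dtype=np.int64)
    index = {b: i for i, b in enumerate(BUCKETS)}
    seen = set()
    for rec in before:
        key = _identity_key(rec.identity)
        if key not in after_by_key:
            raise ValueError(
                f"no re-curated record for {rec.identity.gene_symbol} "
                f"{rec.change.format()}"
            )
        seen.add(key)
        counts[index[_bucket_of(rec)], index[_bucket_of(after_by_key[key])]] += 1
    unmatched = set(after_by_key) - seen
    if unmatched:
        raise ValueError(f"{len(unmatched)} re-curated record(s) have no original")
    return ContingencyTable(counts)


def project_concordance(
    t: ContingencyTable, retained_rate: float, resolved_rate: float
) -> float:
    """Project overall agreement after re-curating every variant.

    Combines the current agreement rate a = trace/total with the fraction
    of concordant interpretations retained on re-curation and the fraction
    of discordant ones resolved into agreement:

        100 * (a * retained_rate + (1 - a) * resolved_rate)

    The result is a projection, not an observed rate.
    """
    if not (0 <= retained_rate <= 1 and 0 <= resolved_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    a = t.trace / t.total
    return 100.0 * (a * retained_rate + (1.0 - a) * resolved_rate)
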