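"""Packaged fixtures from the published cross-resource pilot comparison.

These loaders expose, as package data, the 3x3 cross-classification of
the 4286 missense variants shared by the curated resource and the 2-star
submission records (December 2017 releases), the two re-curation
transition tables for the random 100-variant concordant and discordant
samples, and the evidence profiles of the two worked re-curation examples
(GLI3 p.Ile808Met and ATP7B p.Met645Arg).

:func:`pairs_from_contingency` materializes schematic per-variant matched
pairs realizing a given cross-table, so the counting pipeline can be
exercised end to end from the published totals alone.
"""

from __future__ import annotations

import itertools
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from .concordance import BUCKETS, ContingencyTable, harmonize_class
from .evidence import EvidenceProfile, _profile_from_dict
from .matching import MatchedPair, MatchKey
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

__all__ = [
    "load_global_comparison",
    "load_recuration_concordant",
    "load_recuration_discordant",
    "recuration_rates",
    "load_worked_examples",
    "pairs_from_contingency",
]

#: 5-tier label used when materializing a bucket into a concrete record.
_BUCKET_TO_ACMG = {
    UniProtClass.DISEASE: AcmgClass.PATHOGENIC,
    UniProtClass.POLYMORPHISM: AcmgClass.BENIGN,
    UniProtClass.UNCLASSIFIED: AcmgClass.VUS,
}


def _load_yaml(name: str) -> dict:
    text = resources.files("varconcord.data").joinpath(name).read_text()
    return yaml.safe_load(text)


def _table(section: dict) -> ContingencyTable:
    return ContingencyTable(np.asarray(section["counts"], dtype=np.int64))


def load_global_comparison() -> ContingencyTable:
    """3x3 cross-table of the 4286 shared missense variant interpretations."""
    return _table(_load_yaml("pilot_tables.yaml")["global_comparison"])


def load_recuration_concordant() -> ContingencyTable:
    """Re-curation transitions for the 100-variant concordant sample."""
    return _table(_load_yaml("pilot_tables.yaml")["recuration_concordant"])


def load_recuration_discordant() -> ContingencyTable:
    """Re-curation transitions for the 100-variant discordant sample."""
    return _table(_load_yaml("pilot_tables.yaml")["recuration_discordant"])


def recuration_rates() -> tuple[float, float]:
    """(retained_rate, resolved_rate) observed in the two re-curation samples.

    The retained rate is the fraction of concordant-sample interpretations
    confirmed on re-curation; the resolved rate is the fraction of
    discordant-sample conflicts solved into agreement.
    """
    doc = _load_yaml("pilot_tables.yaml")
    concordant = doc["recuration_concordant"]
    discordant = doc["recuration_discordant"]
    n_conc = int(np.asarray(concordant["counts"]).sum())
    n_disc = int(np.asarray(discordant["counts"]).sum())
    return (
        concordant["confirmed"] / n_conc,
        discordant["solved_conflicts"] / n_disc,
    )


def load_worked_examples() -> list[EvidenceProfile]:
    """Evidence profiles for the GLI3 and ATP7B worked re-curation examples."""
    return [_profile_from_dict(doc) for doc in _load_yaml("worked_examples.yaml")]


def pairs_from_contingency(
    table: ContingencyTable, rng: Optional[np.random.Generator] = None
) -> list[MatchedPair]:
    """Materialize one schematic matched pair per counted interpretation.

    Each cell (i, j) of the table yields ``counts[i, j]`` pairs whose
    curated record carries bucket i and whose aggregate submission record
    carries a 5-tier label harmonizing to bucket j, all with 2-star-style
    submissions. Deterministic; an optional ``rng`` shuffles the output
    order (the tallying statistics are order-invariant).
    """
    pairs: list[MatchedPair] = []
    serial = itertools.count(1)
    disease = DiseaseModel(
        name="Schematic Mendelian disorder",
        inheritance=Inheritance.AUTOSOMAL_DOMINANT,
        is_mendelian=True,
    )
    for i, row_bucket in enumerate(table.labels):
        for j, col_bucket in enumerate(table.labels):
            label = _BUCKET_TO_ACMG[col_bucket]
            for _ in range(int(table.counts[i, j])):
                k = next(serial)
                identity = VariantIdentity(
                    gene_symbol=f"GENE{k:05d}",
                    protein_accession=f"X{k:06d}",
                    rsid=f"rs9{k:08d}",
                    hgvs_p=f"p.Ala{k + 1}Val",
                )
                uniprot = VariantRecord(
                    identity=identity,
                    change=ProteinChange("Ala", k + 1, "Val"),
                    disease=disease,
                    source=Source.UNIPROT,
                    uniprot_class=row_bucket,
                )
                submissions = [
                    ClinVarSubmission(
                        submitter=f"lab-{s}",
                        classification=label,
                        assertion_criteria_provided=True,
                        condition=disease.name,
                    )
                    for s in (1, 2)
                ]
                clinvar = ClinVarAggregateRecord(
                    identity=identity,
                    condition=disease.name,
                    submissions=submissions,
                    review_stars=2,
                    aggregate_class=label,
                )
                pairs.append(MatchedPair(uniprot, clinvar, MatchKey.RSID))
    if rng is not None:
        order = rng.permutation(len(pairs))
        pairs = [pairs[t] for t in order]
    return pairs
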