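import numpy as np
import pytest

from varconcord.models import (
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


def make_disease(**kwargs) -> DiseaseModel:
    defaults = dict(
        name="Test disorder",
        inheritance=Inheritance.AUTOSOMAL_DOMINANT,
        is_mendelian=True,
    )
    defaults.update(kwargs)
    return DiseaseModel(**defaults)


def make_identity(k: int = 1, **kwargs) -> VariantIdentity:
    defaults = dict(
        gene_symbol=f"GENE{k:04d}",
        protein_accession=f"X{k:06d}",
        rsid=f"rs{1000 + k}",
        hgvs_p=f"p.Ala{k + 1}Val",
    )
    defaults.update(kwargs)
    return VariantIdentity(**defaults)


def make_uniprot_record(
    k: int = 1,
    uniprot_class: UniProtClass = UniProtClass.DISEASE,
    disease: DiseaseModel | None = None,
    identity: VariantIdentity | None = None,
) -> VariantRecord:
    identity = identity or make_identity(k)
    return VariantRecord(
        identity=identity,
        change=ProteinChange("Ala", k + 1, "Val"),
        disease=disease or make_disease(),
        source=Source.UNIPROT,
        uniprot_class=uniprot_class,
    )


def make_clinvar_record(
    k: int = 1,
    classification: AcmgClass = AcmgClass.PATHOGENIC,
    stars: int = 2,
    identity: VariantIdentity | None = None,
    condition: str = "Test disorder",
) -> ClinVarAggregateRecord:
    identity = identity or make_identity(k)
    n_submitters = 2 if stars == 2 else 1
    submissions = [
        ClinVarSubmission(
            submitter=f"lab-{i}",
            classification=classification,
            assertion_criteria_provided=stars >= 1,
            condition=condition,
        )
        for i in range(1, n_submitters + 1)
    ]
    return ClinVarAggregateRecord(
        identity=identity,
        condition=condition,
        submissions=submissions,
        expert_panel=stars == 3,
        practice_guideline=stars == 4,
        review_stars=stars,
        aggregate_class=classification,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170412)
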