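"""Frequency thresholds, predictor consensus, functional assays, and the
two worked re-curation examples end to end."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_disease
from varconcord.acmg import EvidenceCode, Strength
from varconcord.evidence import (
    AssayEffect,
    PopulationObservation,
    PredictorVerdict,
    PredictorVerdicts,
    ThresholdUnavailableError,
    classify_profile,
    computational_consensus,
    frequency_evidence,
    functional_evidence,
    max_credible_af,
)
from varconcord.models import AcmgClass, Inheritance
from varconcord.study import load_worked_examples

AD, AR = Inheritance.AUTOSOMAL_DOMINANT, Inheritance.AUTOSOMAL_RECESSIVE


def obs(freq, dataset="ExAC r0.3", hom=0, healthy=False):
    return PopulationObservation(
        dataset=dataset,
        allele_frequency=freq,
        homozygote_count=hom,
        healthy_adult_observed=healthy,
    )


def codes(assignments):
    return {a.code for a in assignments}


class TestMaxCredibleAf:
    def test_rare_dominant_disease(self):
        # prevalence 1e-6, heterogeneity 1, dominant contribution 1/2,
        # full penetrance: closed-form product 5e-7
        d = make_disease(inheritance=AD, prevalence=1e-6)
        assert max_credible_af(d) == pytest.approx(5e-7)

    def test_halving_penetrance_doubles_the_threshold(self):
        d1 = make_disease(inheritance=AD, prevalence=1e-6, penetrance=1.0)
        d2 = make_disease(inheritance=AD, prevalence=1e-6, penetrance=0.5)
        assert max_credible_af(d2) == pytest.approx(2 * max_credible_af(d1))

    def test_missing_prevalence_signals_unavailable(self):
        with pytest.raises(ThresholdUnavailableError):
            max_credible_af(make_disease(inheritance=AD))

    @given(
        prev=st.floats(1e-8, 1e-2),
        factor=st.floats(1.5, 10),
        pen=st.floats(0.05, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_prevalence_and_penetrance(self, prev, factor, pen):
        lo = make_disease(inheritance=AD, prevalence=prev, penetrance=pen)
        hi = make_disease(
            inheritance=AD, prevalence=min(prev * factor, 1.0), penetrance=pen
        )
        assert max_credible_af(hi) >= max_credible_af(lo)
        less_penetrant = make_disease(
            inheritance=AD, prevalence=prev, penetrance=pen / factor
        )
        assert max_credible_af(less_penetrant) >= max_credible_af(lo)


class TestFrequencyEvidence:
    def test_dominant_frequency_far_above_threshold_gives_bs1(self):
        # frequency ~0.2% versus a maximum credible frequency of 5e-7
        d = make_disease(inheritance=AD, prevalence=1e-6)
        out = frequency_evidence([obs(0.002), obs(0.002, "gnomAD r2.0")], d)
        assert EvidenceCode.BS1 in codes(out)
        assert EvidenceCode.BA1 not in codes(out)

    def test_recessive_below_carrier_scale_with_no_homozygote_gives_pm2(self):
        # frequency 0.05% versus carrier allele frequency (1/90)/2 ~ 0.0056
        d = make_disease(
            inheritance=AR, prevalence=1 / 30000, carrier_frequency=1 / 90
        )
        out = frequency_evidence([obs(0.0005)], d)
        assert EvidenceCode.PM2 in codes(out)
        assert EvidenceCode.BS1 not in codes(out)

    def test_frequency_above_five_percent_is_stand_alone(self):
        d = make_disease(inheritance=AD, prevalence=1e-6)
        out = frequency_evidence([obs(0.10)], d)
        assert EvidenceCode.BA1 in codes(out)
        assert EvidenceCode.BS1 not in codes(out)

    def test_healthy_adult_carrier_gives_bs2_for_dominant(self):
        d = make_disease(inheritance=AD, prevalence=1e-6)
        out = frequency_evidence([obs(0.002, healthy=True)], d)
        assert EvidenceCode.BS2 in codes(out)

    def test_recessive_bs2_requires_a_homozygote(self):
        d = make_disease(
            inheritance=AR, prevalence=1 / 30000, carrier_frequency=1 / 90
        )
        no_hom = frequency_evidence([obs(0.0005, healthy=True)], d)
        assert EvidenceCode.BS2 not in codes(no_hom)
        with_hom = frequency_evidence([obs(0.0005, healthy=True, hom=3)], d)
        assert EvidenceCode.BS2 in codes(with_hom)

    def test_no_threshold_disables_bs1_but_keeps_ba1_and_pm2(self):
        d = make_disease(inheritance=AD)  # no prevalence
        assert EvidenceCode.BA1 in codes(frequency_evidence([obs(0.10)], d))
        assert EvidenceCode.PM2 in codes(frequency_evidence([obs(1e-6)], d))
        middle = frequency_evidence([obs(0.001)], d)
        assert codes(middle) == set()

    def test_requires_at_least_one_observation(self):
        with pytest.raises(ValueError):
            frequency_evidence([], make_disease(inheritance=AD, prevalence=1e-6))

    @given(
        freq=st.floats(0, 1),
        prevalence=st.floats(1e-8, 1e-2),
        recessive=st.booleans(),
        hom=st.integers(0, 3),
    )
    @settings(max_examples=300, deadline=None)
    def test_bs1_and_pm2_never_co_emitted(self, freq, prevalence, recessive, hom):
        d = make_disease(
            inheritance=AR if recessive else AD, prevalence=prevalence
        )
        out = codes(frequency_evidence([obs(freq, hom=hom)], d))
        assert not (EvidenceCode.BS1 in out and EvidenceCode.PM2 in out)
        assert not (EvidenceCode.BA1 in out and EvidenceCode.BS1 in out)


class TestComputationalConsensus:
    def test_all_verdict_triples_against_the_concordance_rule(self):
        for triple in itertools.product(list(PredictorVerdict), repeat=3):
            result = computational_consensus(PredictorVerdicts(*triple))
            if all(v is PredictorVerdict.DELETERIOUS for v in triple):
                assert result.code is EvidenceCode.PP3
            elif all(v is PredictorVerdict.TOLERATED for v in triple):
                assert result.code is EvidenceCode.BP4
            else:
                assert result is None


class TestFunctionalEvidence:
    def test_no_effect_in_relevant_assay_is_bs3(self):
        result = functional_evidence(AssayEffect.NO_EFFECT, True)
        assert result.code is EvidenceCode.BS3

    def test_damaging_in_relevant_assay_is_ps3(self):
        assert functional_evidence(AssayEffect.DAMAGING, True).code is EvidenceCode.PS3

    def test_assay_not_reflecting_biology_is_disregarded(self):
        assert functional_evidence(AssayEffect.DAMAGING, False) is None

    def test_equivocal_assay_is_disregarded(self):
        assert functional_evidence(AssayEffect.EQUIVOCAL, True) is None


class TestWorkedExamples:
    """The two packaged re-curation case studies, end to end."""

    def profiles(self):
        gli3, atp7b = load_worked_examples()
        return gli3, atp7b

    def test_gli3_reclassifies_likely_benign(self):
        gli3, _ = self.profiles()
        result = classify_profile(gli3)
        assert result.classification is AcmgClass.LIKELY_BENIGN
        assert not result.conflicting
        used = {a.code: a for a in result.evidence_used}
        assert set(used) == {EvidenceCode.BS1, EvidenceCode.BS2}
        assert used[EvidenceCode.BS2].applied_strength is Strength.SUPPORTING
        assert used[EvidenceCode.BS1].applied_strength is Strength.STRONG

    def test_atp7b_reclassifies_conflicting_vus(self):
        _, atp7b = self.profiles()
        result = classify_profile(atp7b)
        assert result.classification is AcmgClass.VUS
        assert result.conflicting
        assert {a.code for a in result.evidence_used} == {
            EvidenceCode.PM2,
            EvidenceCode.PM3,
            EvidenceCode.BS3,
        }
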