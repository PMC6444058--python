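"""Evidence-combination engine versus an independent rule-table oracle."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from varconcord.acmg import (
    EvidenceAssignment,
    EvidenceCode,
    Polarity,
    Strength,
    StrengthCounts,
    adjust_strength,
    combine_counts,
    combine_evidence,
    parse_report_classification,
    render_report,
)
from varconcord.models import AcmgClass

# ---------------------------------------------------------------------------
# Independent oracle: a direct nested-conditional encoding of the
# guideline's combining table, written without reference to the engine's
# rule file.
# ---------------------------------------------------------------------------


def oracle(vs, s, m, p, ba, bs, bp):
    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s >= 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4)))
    )
    likely_pathogenic = (
        (vs >= 1 and m >= 1)
        or (s >= 1 and m >= 1)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_call = "P" if pathogenic else ("LP" if likely_pathogenic else None)
    benign_call = "B" if benign else ("LB" if likely_benign else None)
    if path_call and benign_call:
        return AcmgClass.VUS, True
    if path_call:
        return AcmgClass.PATHOGENIC if path_call == "P" else AcmgClass.LIKELY_PATHOGENIC, False
    if benign_call:
        return AcmgClass.BENIGN if benign_call == "B" else AcmgClass.LIKELY_BENIGN, False
    mixed = (vs + s + m + p) > 0 and (ba + bs + bp) > 0
    return AcmgClass.VUS, mixed


def test_engine_agrees_with_oracle_over_all_count_vectors():
    """Exhaustive equivalence over all strength-count vectors (counts <= 4)."""
    rng_space = itertools.product(range(5), repeat=7)
    for vs, s, m, p, ba, bs, bp in rng_space:
        counts = StrengthCounts(
            very_strong=vs, strong=s, moderate=m, supporting=p,
            stand_alone=ba, benign_strong=bs, benign_supporting=bp,
        )
        got_class, _, got_conflict = combine_counts(counts)
        want_class, want_conflict = oracle(vs, s, m, p, ba, bs, bp)
        assert got_class is want_class, (vs, s, m, p, ba, bs, bp)
        assert got_conflict == want_conflict, (vs, s, m, p, ba, bs, bp)


# ---------------------------------------------------------------------------
# Worked combinations
# ---------------------------------------------------------------------------


def A(code, strength=None, justification="test rationale"):
    return EvidenceAssignment(
        EvidenceCode[code],
        applied_strength=strength,
        justification=justification,
    )


class TestCombineEvidence:
    def test_strong_plus_supporting_benign_is_likely_benign(self):
        # the GLI3 outcome: BS1 at full strength, BS2 down-weighted
        result = combine_evidence(
            [A("BS1"), A("BS2", Strength.SUPPORTING)]
        )
        assert result.classification is AcmgClass.LIKELY_BENIGN
        assert not result.conflicting

    def test_mixed_polarity_moderates_with_strong_benign_is_conflicting_vus(self):
        # the ATP7B outcome: PM2 + PM3 fire nothing, BS3 fires nothing,
        # and the polarities cannot be reconciled
        result = combine_evidence([A("PM2"), A("PM3"), A("BS3")])
        assert result.classification is AcmgClass.VUS
        assert result.conflicting

    def test_no_evidence_is_uncertain(self):
        result = combine_evidence([])
        assert result.classification is AcmgClass.VUS
        assert not result.conflicting

    def test_very_strong_plus_strong_is_pathogenic(self):
        result = combine_evidence([A("PVS1"), A("PS1")])
        assert result.classification is AcmgClass.PATHOGENIC

    def test_stand_alone_frequency_is_benign(self):
        assert combine_evidence([A("BA1")]).classification is AcmgClass.BENIGN

    def test_duplicated_codes_counted_once(self):
        # two citations of BP4 are one criterion, not two
        result = combine_evidence([A("BP4"), A("BP4")])
        assert result.classification is AcmgClass.VUS

    @given(
        codes=st.lists(st.sampled_from(list(EvidenceCode)), min_size=0, max_size=8),
        seed=st.randoms(use_true_random=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_permutation_invariance(self, codes, seed):
        evidence = [EvidenceAssignment(c) for c in codes]
        shuffled = list(evidence)
        seed.shuffle(shuffled)
        assert combine_evidence(evidence) == combine_evidence(shuffled)


_RANK = {
    AcmgClass.BENIGN: 0,
    AcmgClass.LIKELY_BENIGN: 1,
    AcmgClass.VUS: 2,
    AcmgClass.LIKELY_PATHOGENIC: 3,
    AcmgClass.PATHOGENIC: 4,
}

_PATHOGENIC_CODES = [c for c in EvidenceCode if c.polarity is Polarity.PATHOGENIC]
_BENIGN_CODES = [c for c in EvidenceCode if c.polarity is Polarity.BENIGN]


@given(
    codes=st.lists(st.sampled_from(list(EvidenceCode)), max_size=7),
    extra=st.sampled_from(_PATHOGENIC_CODES),
)
@settings(max_examples=300, deadline=None)
def test_adding_pathogenic_evidence_never_moves_toward_benign(codes, extra):
    before = combine_evidence([EvidenceAssignment(c) for c in codes])
    after = combine_evidence([EvidenceAssignment(c) for c in codes + [extra]])
    assert _RANK[after.classification] >= _RANK[before.classification]


@given(
    codes=st.lists(st.sampled_from(list(EvidenceCode)), max_size=7),
    extra=st.sampled_from(_BENIGN_CODES),
)
@settings(max_examples=300, deadline=None)
def test_adding_benign_evidence_never_moves_toward_pathogenic(codes, extra):
    before = combine_evidence([EvidenceAssignment(c) for c in codes])
    after = combine_evidence([EvidenceAssignment(c) for c in codes + [extra]])
    assert _RANK[after.classification] <= _RANK[before.classification]


class TestAdjustStrength:
    def test_downgrade_records_default_and_applied(self):
        adjusted = adjust_strength(
            A("BS2"), Strength.SUPPORTING, "penetrance not 100%"
        )
        assert adjusted.applied_strength is Strength.SUPPORTING
        assert adjusted.default_strength is Strength.STRONG
        assert adjusted.polarity is Polarity.BENIGN

    def test_same_strength_with_note_is_allowed(self):
        adjusted = adjust_strength(A("PM2"), Strength.MODERATE, "kept at default")
        assert adjusted.applied_strength is Strength.MODERATE
        assert adjusted.justification == "kept at default"

    def test_empty_justification_is_an_error(self):
        with pytest.raises(ValueError):
            adjust_strength(A("BS2"), Strength.SUPPORTING, "   ")

    def test_polarity_cannot_be_flipped(self):
        # stand-alone is a benign-only strength; and polarity is derived
        # from the code, so a benign code stays benign after adjustment
        with pytest.raises(ValueError):
            adjust_strength(A("PS1"), Strength.STAND_ALONE, "why not")
        adjusted = adjust_strength(A("BS3"), Strength.SUPPORTING, "weak assay")
        assert adjusted.polarity is Polarity.BENIGN


class TestReport:
    def test_report_names_evidence_and_final_class(self):
        result = combine_evidence([A("BS1"), A("BS2", Strength.SUPPORTING)])
        text = render_report(result)
        assert "BS1" in text and "BS2" in text
        assert "Likely benign" in text

    def test_empty_evidence_report_states_no_criteria(self):
        text = render_report(combine_evidence([]))
        assert "no criteria met" in text
        assert "Uncertain significance" in text

    def test_deterministic_bytes(self):
        result = combine_evidence([A("PM2"), A("PM3"), A("BS3")])
        assert render_report(result) == render_report(result)

    @given(codes=st.lists(st.sampled_from(list(EvidenceCode)), max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_render_then_parse_recovers_classification(self, codes):
        result = combine_evidence([EvidenceAssignment(c) for c in codes])
        assert parse_report_classification(render_report(result)) is result.classification
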