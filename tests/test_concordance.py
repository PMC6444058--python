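"""Concordance statistics: harmonization, tables, the union-denominator
formula, re-curation transitions and the projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_clinvar_record, make_uniprot_record
from varconcord.concordance import (
    BUCKETS,
    ContingencyTable,
    UndefinedCategoryError,
    build_contingency,
    build_transition,
    category_concordance,
    harmonize_class,
    overall_concordance,
    project_concordance,
    round_half_away,
)
from varconcord.matching import match_variants
from varconcord.models import AcmgClass, Source, UniProtClass, VariantRecord
from varconcord.study import load_global_comparison, load_recuration_concordant

D, P, U = UniProtClass.DISEASE, UniProtClass.POLYMORPHISM, UniProtClass.UNCLASSIFIED


@pytest.mark.parametrize(
    "five_tier, bucket",
    [
        (AcmgClass.PATHOGENIC, D),
        (AcmgClass.LIKELY_PATHOGENIC, D),
        (AcmgClass.BENIGN, P),
        (AcmgClass.LIKELY_BENIGN, P),
        (AcmgClass.VUS, U),
    ],
)
def test_harmonize_class_total_mapping(five_tier, bucket):
    assert harmonize_class(five_tier) is bucket


def tables(rng, n=1000, max_cell=60):
    for _ in range(n):
        counts = rng.integers(0, max_cell, size=(3, 3))
        if counts.sum() > 0:
            yield ContingencyTable(counts)


class TestBuildContingency:
    def make_pairs(self, assignments):
        pairs = []
        for k, (u_class, c_class) in enumerate(assignments, start=1):
            u = make_uniprot_record(k, uniprot_class=u_class)
            c = make_clinvar_record(k, classification=c_class)
            pairs.extend(match_variants([u], [c]))
        return pairs

    def test_two_diagonal_pairs(self):
        t = build_contingency(
            self.make_pairs([(D, AcmgClass.PATHOGENIC), (P, AcmgClass.BENIGN)])
        )
        assert t.trace == 2 and t.total == 2

    def test_matches_brute_force_tally(self, rng):
        classes = list(AcmgClass)
        assignments = [
            (BUCKETS[rng.integers(3)], classes[rng.integers(5)]) for _ in range(50)
        ]
        t = build_contingency(self.make_pairs(assignments))
        expected = np.zeros((3, 3), dtype=int)
        for u_class, c_class in assignments:
            expected[BUCKETS.index(u_class), BUCKETS.index(harmonize_class(c_class))] += 1
        assert (t.counts == expected).all()
        assert t.total == 50

    def test_missing_classification_is_an_error_naming_the_pair(self):
        pairs = self.make_pairs([(D, AcmgClass.PATHOGENIC)])
        pairs[0].clinvar.aggregate_class = None
        with pytest.raises(ValueError, match="GENE0001"):
            build_contingency(pairs)


class TestCategoryConcordance:
    def test_published_polymorphism_concordance_is_86(self):
        t = load_global_comparison()
        value = category_concordance(t, P)
        assert value == pytest.approx(100 * 2328 / (2328 + 46 + 128 + 111 + 81))
        assert round_half_away(value) == 86

    def test_published_disease_concordance_is_81(self):
        assert round_half_away(category_concordance(load_global_comparison(), D)) == 81

    def test_published_uncertain_concordance_is_24(self):
        assert round_half_away(category_concordance(load_global_comparison(), U)) == 24

    def test_diagonal_only_table_is_100_per_bucket(self):
        t = ContingencyTable(np.diag([5, 7, 9]))
        for bucket in BUCKETS:
            assert category_concordance(t, bucket) == 100.0

    def test_empty_bucket_union_is_undefined(self):
        t = ContingencyTable(np.diag([5, 7, 0]))
        with pytest.raises(UndefinedCategoryError):
            category_concordance(t, U)

    def test_at_most_100_and_equals_100_iff_no_off_diagonal_mass(self, rng):
        for t in tables(rng, n=300):
            for bucket in BUCKETS:
                i = BUCKETS.index(bucket)
                off = t.row_total(bucket) + t.col_total(bucket) - 2 * t.diagonal(bucket)
                try:
                    value = category_concordance(t, bucket)
                except UndefinedCategoryError:
                    continue
                assert value <= 100.0
                assert (value == 100.0) == (off == 0)


class TestOverallConcordance:
    def test_published_table_gives_3771_of_4286_88_percent(self):
        report = overall_concordance(load_global_comparison())
        assert report.n_agree == 3771
        assert report.n_total == 4286
        assert round_half_away(report.overall) == 88

    def test_identity_table_is_100(self):
        report = overall_concordance(ContingencyTable(np.diag([1, 2, 3])))
        assert report.overall == 100.0

    def test_random_tables_match_trace_over_total(self, rng):
        for t in tables(rng):
            report = overall_concordance(t)
            assert report.overall == pytest.approx(
                100 * np.trace(t.counts) / t.counts.sum()
            )
            assert report.n_agree <= report.n_total

    def test_invariant_under_simultaneous_row_col_permutation(self, rng):
        for t in tables(rng, n=50):
            perm = rng.permutation(3)
            permuted = ContingencyTable(
                t.counts[np.ix_(perm, perm)],
                tuple(BUCKETS[i] for i in perm),
            )
            assert overall_concordance(permuted).overall == pytest.approx(
                overall_concordance(t).overall
            )

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            overall_concordance(ContingencyTable(np.zeros((3, 3), dtype=int)))


class TestBuildTransition:
    def records(self, buckets, source=Source.UNIPROT, recurated=None):
        out = []
        for k, bucket in enumerate(buckets, start=1):
            rec = make_uniprot_record(k, uniprot_class=bucket)
            if recurated is not None:
                rec = VariantRecord(
                    identity=rec.identity,
                    change=rec.change,
                    disease=rec.disease,
                    source=Source.CLINVAR,
                    acmg_class=recurated[k - 1],
                )
            out.append(rec)
        return out

    def test_no_changes_gives_diagonal_table(self):
        before = self.records([D, P, U, D])
        after = self.records(
            [D, P, U, D],
            recurated=[
                AcmgClass.PATHOGENIC,
                AcmgClass.BENIGN,
                AcmgClass.VUS,
                AcmgClass.LIKELY_PATHOGENIC,
            ],
        )
        t = build_transition(before, after)
        assert t.trace == 4 and t.total == 4

    def test_matches_brute_force_tally(self, rng):
        classes = list(AcmgClass)
        orig = [BUCKETS[rng.integers(3)] for _ in range(20)]
        new = [classes[rng.integers(5)] for _ in range(20)]
        t = build_transition(
            self.records(orig), self.records(orig, recurated=new)
        )
        expected = np.zeros((3, 3), dtype=int)
        for o, n in zip(orig, new):
            expected[BUCKETS.index(o), BUCKETS.index(harmonize_class(n))] += 1
        assert (t.counts == expected).all()

    def test_unmatched_identity_is_an_error(self):
        before = self.records([D, P])
        after = self.records([D], recurated=[AcmgClass.PATHOGENIC])
        with pytest.raises(ValueError):
            build_transition(before, after)

    def test_published_concordant_sample_transitions(self):
        t = load_recuration_concordant()
        assert [t.diagonal(b) for b in BUCKETS] == [54, 38, 4]
        assert t.total - t.trace == 4
        assert t.counts[0, 2] == 4  # the only off-diagonal: disease -> uncertain


class TestProjection:
    def test_published_rates_project_to_94(self):
        value = project_concordance(load_global_comparison(), 96 / 100, 78 / 100)
        assert round_half_away(value) == 94

    def test_perfect_rates_project_to_100(self):
        assert project_concordance(load_global_comparison(), 1.0, 1.0) == 100.0

    @given(
        cells=st.lists(st.integers(0, 50), min_size=9, max_size=9),
        retained=st.floats(0, 1),
        resolved=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_closed_form(self, cells, retained, resolved):
        counts = np.array(cells).reshape(3, 3)
        if counts.sum() == 0:
            return
        t = ContingencyTable(counts)
        a = np.trace(counts) / counts.sum()
        assert project_concordance(t, retained, resolved) == pytest.approx(
            100 * (a * retained + (1 - a) * resolved)
        )
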