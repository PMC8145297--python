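"""Endpoint-dilution titration, fold comparisons, and cohort summaries."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rtquic.datasets import load_month1_colon, load_study_cohort, load_table1
from rtquic.model import SampleMeta, ValidationError
from rtquic.titration import (
    endpoint_dilution,
    fold_difference,
    format_endpoint,
    parse_endpoint,
    seeding_rank,
    summarize_cohort,
)


def _series(**calls):
    """calls like m3='positive', m4='negative' -> {-3: 'positive', ...}"""
    return {-int(k[1:]): v for k, v in calls.items()}


class TestEndpointDilution:
    def test_full_series_endpoint_is_most_dilute_positive(self):
        t = endpoint_dilution(
            {e: "positive" for e in range(-3, -9, -1)}, sample_id="brain"
        )
        assert t.endpoint_exponent == -8 and t.monotone

    def test_truncating_negative_tail(self):
        t = endpoint_dilution(
            _series(m3="positive", m4="positive", m5="negative"), "s"
        )
        assert t.endpoint_exponent == -4
        assert t.monotone and not t.inhibited_low_dilution_flag

    def test_all_negative_is_nd(self):
        t = endpoint_dilution(_series(m3="negative", m4="negative"), "s")
        assert t.is_nd and t.endpoint_exponent is None

    def test_inhibited_low_dilution_flagged(self):
        t = endpoint_dilution(_series(m3="negative", m4="positive"), "s")
        assert t.endpoint_exponent == -4
        assert t.inhibited_low_dilution_flag and not t.monotone

    def test_gap_in_series_is_non_monotone(self):
        t = endpoint_dilution(
            _series(m3="positive", m4="negative", m5="positive"), "s"
        )
        assert t.endpoint_exponent == -5 and not t.monotone

    def test_requires_base_dilution_and_nonempty_map(self):
        with pytest.raises(ValidationError):
            endpoint_dilution({}, "s")
        with pytest.raises(ValidationError):
            endpoint_dilution(_series(m4="positive"), "s")
        # relaxed when explicitly allowed
        t = endpoint_dilution(_series(m4="positive"), "s", require_exponent=None)
        assert t.endpoint_exponent == -4


class TestFoldDifference:
    def test_brain_vs_colon_three_decades(self):
        brain = endpoint_dilution(
            {e: "positive" for e in range(-3, -9, -1)}, "brain"
        )
        colon = endpoint_dilution(
            {-3: "positive", -4: "positive", -5: "positive"}, "colon"
        )
        fold = fold_difference(brain, colon)
        assert fold.defined and fold.fold == pytest.approx(1000.0)

    def test_equal_endpoints_give_unity(self):
        a = endpoint_dilution(_series(m3="positive"), "a")
        b = endpoint_dilution(_series(m3="positive"), "b")
        assert fold_difference(a, b).fold == pytest.approx(1.0)

    def test_nd_propagates_as_undefined_never_a_number(self):
        pos = endpoint_dilution(_series(m3="positive"), "a")
        nd = endpoint_dilution(_series(m3="negative"), "b")
        fold = fold_difference(pos, nd)
        assert not fold.defined and fold.fold is None and fold.log10_fold is None

    @given(ea=st.integers(min_value=-10, max_value=-3),
           eb=st.integers(min_value=-10, max_value=-3))
    def test_reciprocal_property(self, ea, eb):
        a = endpoint_dilution({e: "positive" for e in range(-3, ea - 1, -1)}, "a")
        b = endpoint_dilution({e: "positive" for e in range(-3, eb - 1, -1)}, "b")
        ab, ba = fold_difference(a, b), fold_difference(b, a)
        assert ab.fold * ba.fold == pytest.approx(1.0)


def test_seeding_rank_total_order_never_numeric_nd():
    ranked = [None, -3, -4, -5, -8]
    ranks = [seeding_rank(e) for e in ranked]
    assert ranks == sorted(ranks) and len(set(ranks)) == len(ranks)


@pytest.mark.parametrize("exponent", [None, -3, -5, -8])
def test_endpoint_formatting_round_trip(exponent):
    assert parse_endpoint(format_endpoint(exponent)) == exponent


class TestCohortSummary:
    def test_study_fixture_summary_facts(self):
        titrations, metas = load_table1()
        summary = summarize_cohort(titrations, metas)
        counts = summary.positive_counts.set_index(["age_months", "tissue"])
        assert counts.loc[(6, "brain"), "n_positive"] == 1
        assert counts.loc[(3, "colon"), "n_positive"] == 3
        twelve_colon = summary.records.query(
            "age_months == 12 and tissue == 'colon' and genotype == 'transgenic'"
        )
        assert set(twelve_colon["endpoint_exponent"]) == {-5}
        assert summary.most_dilute_endpoint["brain"] == -8
        assert not summary.contamination_warning

    def test_one_month_data_sets_earliest_colon_age(self):
        titrations, metas = load_study_cohort()
        summary = summarize_cohort(titrations, metas)
        assert summary.earliest_positive_age["colon"] == 3
        assert summary.earliest_positive_age["brain"] == 6

    def test_six_month_colon_exceeds_brain_in_all_subjects(self):
        titrations, metas = load_table1()
        summary = summarize_cohort(titrations, metas)
        six = summary.tissue_comparison.query("age_months == 6")
        assert list(six["more_dilute_tissue"]) == ["colon"] * 3

    def test_permutation_invariance(self):
        titrations, metas = load_study_cohort()
        base = summarize_cohort(titrations, metas)
        for order in itertools.islice(
            itertools.permutations(titrations), 0, 6, 2
        ):
            shuffled = {k: titrations[k] for k in order}
            again = summarize_cohort(shuffled, metas)
            assert again.records.equals(base.records)
            assert again.positive_counts.equals(base.positive_counts)

    def test_all_nd_cohort_has_no_positives_anywhere(self):
        titrations, metas = load_month1_colon()
        summary = summarize_cohort(titrations, metas)
        assert summary.positive_counts["n_positive"].sum() == 0
        assert summary.earliest_positive_age["colon"] is None
        assert summary.most_dilute_endpoint["colon"] is None

    def test_non_nd_control_raises_contamination_warning(self):
        titrations, metas = load_month1_colon()
        bad = dict(titrations)
        bad["1M-Con-colon"] = endpoint_dilution(
            {-3: "positive", -4: "negative"}, "1M-Con-colon"
        )
        summary = summarize_cohort(bad, metas)
        assert summary.contamination_warning
        assert summary.control_failures == ["1M-Con-colon"]

    def test_conflicting_duplicate_records_rejected(self):
        titrations, metas = load_month1_colon()
        dup_t = dict(titrations)
        dup_m = dict(metas)
        dup_t["dup"] = endpoint_dilution({-3: "positive"}, "dup")
        dup_m["dup"] = SampleMeta(
            sample_id="dup", subject_id="1M-#1", age_months=1,
            genotype="transgenic", tissue="colon",
        )
        with pytest.raises(ValidationError, match="conflicting"):
            summarize_cohort(dup_t, dup_m)
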