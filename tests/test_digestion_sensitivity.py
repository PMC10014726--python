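"""Relative-change arithmetic and the replicate/clone classification rules."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epitope_audit.digestion_sensitivity import (
    Category,
    ExclusionReason,
    ReplicateCall,
    SensitivityConfig,
    apply_inclusion_criteria,
    average_technical_repeats,
    classify_clone,
    classify_fixture_clones,
    classify_replicate,
    relative_change,
    summarize_cohort,
)
from epitope_audit.flow_model import (
    ClassificationError,
    DataError,
    UndefinedRCError,
)
from .conftest import make_measurement


class TestRelativeChange:
    @pytest.mark.parametrize("undig, dig, expected", [
        (40.0, 20.0, 50.0),
        (10.0, 10.0, 0.0),
        (60.0, 0.0, 100.0),
        (25.0, 72.0, -188.0),
    ])
    def test_worked_examples(self, undig, dig, expected):
        assert relative_change(undig, dig) == pytest.approx(expected)

    def test_undefined_for_zero_undigested(self):
        with pytest.raises(UndefinedRCError):
            relative_change(0.0, 5.0)

    @settings(max_examples=200, deadline=None)
    @given(undig=st.floats(min_value=1e-6, max_value=100),
           dig=st.floats(min_value=0, max_value=100))
    def test_bounded_above_by_100(self, undig, dig):
        rc = relative_change(undig, dig)
        assert rc <= 100.0
        if dig == 0.0:
            assert rc == 100.0

    def test_bound_holds_at_scale(self):
        rng = np.random.default_rng(0)
        undig = rng.uniform(1e-6, 100, 100_000)
        dig = rng.uniform(0, 100, 100_000)
        rc = 100.0 * (undig - dig) / undig
        computed = [relative_change(u, d)
                    for u, d in zip(undig[:100], dig[:100])]
        np.testing.assert_allclose(computed, rc[:100])
        assert rc.max() <= 100.0


class TestAverageTechnicalRepeats:
    def test_same_day_repeats_collapse_to_mean(self):
        ms = [
            make_measurement(pct_pos_undigested=40, pct_pos_digested=20),
            make_measurement(pct_pos_undigested=44, pct_pos_digested=22),
        ]
        out = average_technical_repeats(ms)
        assert len(out) == 1
        assert out[0].pct_pos_undigested == pytest.approx(42)
        assert out[0].pct_pos_digested == pytest.approx(21)

    def test_single_measurement_unchanged(self):
        m = make_measurement()
        assert average_technical_repeats([m]) == [m]

    def test_different_days_not_collapsed(self):
        ms = [make_measurement(experiment_day="day1"),
              make_measurement(experiment_day="day2")]
        assert len(average_technical_repeats(ms)) == 2

    def test_different_donors_not_collapsed(self):
        ms = [make_measurement(donor_id="donor1"),
              make_measurement(donor_id="donor2")]
        assert len(average_technical_repeats(ms)) == 2

    def test_detectability_is_or_of_group(self):
        ms = [make_measurement(positive_detected_digested=False),
              make_measurement(positive_detected_digested=True)]
        assert average_technical_repeats(ms)[0].positive_detected_digested


class TestInclusionCriteria:
    def test_single_donor_clone_fully_excluded(self):
        ms = [make_measurement(donor_id="donor1", experiment_day=f"day{i}")
              for i in range(3)]
        calls = apply_inclusion_criteria(ms)
        assert all(c.category is Category.EXCLUDED for c in calls)
        assert all(c.exclusion_reason is ExclusionReason.TOO_FEW_DONORS
                   for c in calls)

    def test_zero_undigested_positivity_excluded(self):
        ms = [make_measurement(donor_id=f"donor{i}") for i in (1, 2)]
        ms[0] = make_measurement(donor_id="donor1", pct_pos_undigested=0.0,
                                 pct_pos_digested=0.0)
        calls = apply_inclusion_criteria(ms)
        assert calls[0].exclusion_reason is \
            ExclusionReason.NO_POSITIVE_IN_UNDIGESTED
        assert calls[1].category is not Category.EXCLUDED

    def test_insufficient_activation_excluded(self):
        ms = [make_measurement(donor_id=f"donor{i}", activation_required=True,
                               cd69_pct_activated=cd69)
              for i, cd69 in ((1, 5.0), (2, 60.0))]
        calls = apply_inclusion_criteria(ms)
        assert calls[0].exclusion_reason is \
            ExclusionReason.INSUFFICIENT_ACTIVATION
        assert calls[1].category is not Category.EXCLUDED

    def test_activation_without_cd69_is_a_data_error(self):
        ms = [make_measurement(donor_id=f"donor{i}", activation_required=True)
              for i in (1, 2)]
        with pytest.raises(DataError):
            apply_inclusion_criteria(ms)


class TestClassifyReplicate:
    @pytest.mark.parametrize("undig, dig, expected", [
        (30.0, 3.0, Category.SENSITIVE),            # rc 90
        (30.0, 21.0, Category.PARTIALLY_SENSITIVE),  # rc 30
        (30.0, 27.0, Category.INSENSITIVE),          # rc 10
        (40.0, 20.0, Category.SENSITIVE),            # rc exactly 50
        (40.0, 30.0, Category.PARTIALLY_SENSITIVE),  # rc exactly 25
        (40.0, 30.4, Category.INSENSITIVE),          # rc just below 25
    ])
    def test_threshold_bands(self, undig, dig, expected):
        call = classify_replicate(make_measurement(
            pct_pos_undigested=undig, pct_pos_digested=dig))
        assert call.category is expected
        assert not call.rare_population_rule_applied

    def test_rare_population_visible_is_insensitive_despite_high_rc(self):
        call = classify_replicate(make_measurement(
            pct_pos_undigested=4.0, pct_pos_digested=0.5,
            positive_detected_digested=True))
        assert call.category is Category.INSENSITIVE
        assert call.rare_population_rule_applied
        assert call.rc == pytest.approx(87.5)

    def test_rare_population_invisible_is_sensitive(self):
        call = classify_replicate(make_measurement(
            pct_pos_undigested=4.0, pct_pos_digested=0.5,
            positive_detected_digested=False))
        assert call.category is Category.SENSITIVE
        assert call.rare_population_rule_applied

    def test_mfi_variant(self):
        m = make_measurement(mfi_undigested=1000.0, mfi_digested=400.0,
                             pct_pos_undigested=30, pct_pos_digested=29)
        call = classify_replicate(m, SensitivityConfig(use_mfi=True))
        assert call.rc == pytest.approx(60.0)
        assert call.category is Category.SENSITIVE


def oracle_clone_category(categories):
    """Brute-force restatement of the published majority/tie text:
    a category holding a strict majority of replicates wins; a 50% split
    (full/partial, partial/insensitive, or the uncovered full/insensitive
    case) and any other majority-free pattern is partially sensitive."""
    n = len(categories)
    counts = Counter(categories)
    for cat, k in counts.items():
        if k > n / 2:
            return cat
    return Category.PARTIALLY_SENSITIVE


def calls_from_categories(categories):
    calls = []
    for i, cat in enumerate(categories):
        undig, dig = {
            Category.SENSITIVE: (40.0, 10.0),
            Category.PARTIALLY_SENSITIVE: (40.0, 28.0),
            Category.INSENSITIVE: (40.0, 38.0),
        }[cat]
        m = make_measurement(donor_id=f"donor{i % 2 + 1}",
                             experiment_day=f"day{i}",
                             pct_pos_undigested=undig, pct_pos_digested=dig)
        calls.append(classify_replicate(m))
    assert [c.category for c in calls] == list(categories)
    return calls


class TestClassifyClone:
    @pytest.mark.parametrize("props, expected", [
        ((4, 0, 0), Category.SENSITIVE),              # 100/0/0
        ((2, 1, 0), Category.SENSITIVE),              # 67/33/0
        ((0, 1, 1), Category.PARTIALLY_SENSITIVE),    # 0/50/50 tie
        ((1, 1, 3), Category.INSENSITIVE),            # 20/20/60
        ((1, 0, 1), Category.PARTIALLY_SENSITIVE),    # 50/0/50 extension
        ((1, 1, 1), Category.PARTIALLY_SENSITIVE),    # three-way tie
    ])
    def test_majority_and_tie_rules(self, props, expected):
        cats = ([Category.SENSITIVE] * props[0]
                + [Category.PARTIALLY_SENSITIVE] * props[1]
                + [Category.INSENSITIVE] * props[2])
        call = classify_clone(calls_from_categories(cats))
        assert call.category is expected
        assert call.prop_sensitive == pytest.approx(100 * props[0] / sum(props))

    def test_exhaustive_oracle_equivalence(self):
        """classify_clone agrees with the brute-force majority/tie oracle on
        every category multiset of size 1..6."""
        cats = (Category.SENSITIVE, Category.PARTIALLY_SENSITIVE,
                Category.INSENSITIVE)
        n_cases = 0
        for size in range(1, 7):
            for combo in itertools.combinations_with_replacement(cats, size):
                call = classify_clone(calls_from_categories(list(combo)))
                assert call.category is oracle_clone_category(combo), combo
                n_cases += 1
        assert n_cases == 83

    def test_permutation_invariance(self):
        cats = [Category.SENSITIVE, Category.INSENSITIVE,
                Category.PARTIALLY_SENSITIVE, Category.SENSITIVE]
        rng = np.random.default_rng(0)
        reference = classify_clone(calls_from_categories(cats)).category
        for _ in range(5):
            rng.shuffle(cats)
            assert classify_clone(
                calls_from_categories(cats)).category is reference

    def test_excluded_replicates_never_counted(self):
        calls = calls_from_categories([Category.SENSITIVE,
                                       Category.INSENSITIVE,
                                       Category.INSENSITIVE])
        excluded = ReplicateCall(
            measurement=make_measurement(), rc=None,
            category=Category.EXCLUDED,
            exclusion_reason=ExclusionReason.NO_POSITIVE_IN_UNDIGESTED)
        call = classify_clone(calls + [excluded] * 5)
        assert call.n_replicates_included == 3
        assert call.category is Category.INSENSITIVE

    def test_no_included_replicates_is_an_error(self):
        excluded = ReplicateCall(
            measurement=make_measurement(), rc=None,
            category=Category.EXCLUDED,
            exclusion_reason=ExclusionReason.TOO_FEW_DONORS)
        with pytest.raises(ClassificationError):
            classify_clone([excluded])


class TestFixtureClassification:
    def test_twelve_sensitive_clones_eight_totalseqc(self, fixtures):
        calls = classify_fixture_clones(fixtures.table2)
        sensitive = [c for c in calls if c.category is Category.SENSITIVE]
        assert len(sensitive) == 12
        assert sum(c.is_totalseqc for c in sensitive) == 8

    @pytest.mark.parametrize("clone, expected", [
        ("RPA-T4", Category.SENSITIVE),
        ("OKT4", Category.INSENSITIVE),
        ("B1.49.9", Category.PARTIALLY_SENSITIVE),
        ("M-A251", Category.INSENSITIVE),
        ("11A9", Category.PARTIALLY_SENSITIVE),
        ("PD1.3", Category.PARTIALLY_SENSITIVE),
    ])
    def test_individual_clone_calls(self, fixtures, clone, expected):
        calls = {c.clone: c for c in classify_fixture_clones(fixtures.table2)}
        assert calls[clone].category is expected


class TestSummarizeCohort:
    def test_fixture_summary_counts(self, fixtures):
        report = summarize_cohort(classify_fixture_clones(fixtures.table2))
        assert report.clone_counts["sensitive"] == 12
        assert report.clone_counts_totalseqc["sensitive"] == 8
        assert report.clone_table.shape[0] == 20
        assert (report.clone_table[["pct_sensitive", "pct_partial",
                                    "pct_not"]].sum(axis=1)
                .between(99, 101).all())

    def test_replicate_aggregates(self):
        cats = [Category.SENSITIVE] * 2 + [Category.INSENSITIVE] * 2
        calls = calls_from_categories(cats)
        report = summarize_cohort([classify_clone(calls)], calls)
        rcs = sorted(c.rc for c in calls)
        assert report.replicate_summary["n_included"] == 4
        assert report.replicate_summary["median_rc"] == \
            pytest.approx(np.median(rcs))
        assert report.replicate_summary["min_rc"] == pytest.approx(min(rcs))

    def test_lineage_grouping_counts(self, fixtures):
        calls = classify_fixture_clones(fixtures.table2)
        lineages = {c.marker: frozenset({"T"}) for c in calls}
        lineages["CD25"] = frozenset({"T", "NK/ILC"})
        report = summarize_cohort(calls, marker_lineages=lineages)
        table = report.lineage_counts.set_index("lineages")
        assert table.loc["NK/ILC+T", "n_clones"] == 5   # the 5 CD25 clones
        assert table["n_clones"].sum() == 20
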