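"""Discordance detection, the review queue, and the heterogeneity taxonomy."""

import pytest

from tma_concord import (
    CoreMeasurement,
    HeterogeneityCategory,
    Marker,
    build_review_queue,
    classify_heterogeneity,
    collapse_case,
    detect_discordance,
    summarize_heterogeneity,
)
from tma_concord.discordance import cross_marker_cooccurrence, is_review_eligible


def erpr_case(percents, marker=Marker.ER, case="c1", nuclei=None):
    nuclei = nuclei or [500] * len(percents)
    cores = [
        CoreMeasurement(case_id=case, core_id=f"k{i}", marker=marker,
                        percent_positive=p, tumor_nuclei=n)
        for i, (p, n) in enumerate(zip(percents, nuclei))
    ]
    return collapse_case(cores)


def her2_case(profiles, case="c1"):
    """profiles: list of (pct_3, pct_2) per core."""
    cores = [
        CoreMeasurement(case_id=case, core_id=f"k{i}", marker=Marker.HER2,
                        pct_01=100.0 - p3 - p2, pct_2=p2, pct_3=p3, tumor_nuclei=500)
        for i, (p3, p2) in enumerate(profiles)
    ]
    return collapse_case(cores)


class TestDetectDiscordance:
    def test_straddling_one_percent_is_discordant_on_primary_scale(self):
        case = erpr_case([0.5, 4.0])
        assert detect_discordance(case, "primary")
        assert not detect_discordance(case, "alternative_10pct")  # both < 10 %

    def test_identical_her2_categories_concordant(self):
        assert not detect_discordance(her2_case([(0, 0), (2, 5), (1, 3)]))

    def test_differing_her2_categories_discordant(self):
        assert detect_discordance(her2_case([(5, 20), (15, 10)]))  # 2+ vs 3+

    def test_requires_two_cores(self):
        case = erpr_case([5.0, 5.0])
        object.__setattr__(case, "n_cores", 1)
        with pytest.raises(ValueError):
            detect_discordance(case)

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError):
            detect_discordance(erpr_case([1, 2]), scale="bogus")


class TestReviewQueue:
    def test_case_negative_discordant_not_queued(self):
        # discordant around 1 % but weighted 0.7 % -> negative case, noise only
        case = erpr_case([0.2, 1.2], nuclei=[500, 500])
        assert case.discordant and case.case_status == "negative"
        assert not is_review_eligible(case)

    def test_her2_without_3plus_core_not_queued(self):
        case = her2_case([(0, 2), (3, 20)])  # 0/1+ vs 2+
        assert case.discordant and not is_review_eligible(case)

    def test_positive_discordant_queued(self):
        case = erpr_case([0.5, 12.0], marker=Marker.PR)
        assert is_review_eligible(case)

    def test_queue_sorted_by_expression_then_id(self):
        cases = [
            erpr_case([0.5, 30.0], case="b"),
            erpr_case([0.5, 5.0], case="a"),
            erpr_case([0.5, 30.0], case="a2"),
        ]
        queue = build_review_queue(cases)
        assert [c.case_id for c in queue] == ["a", "a2", "b"]
        assert queue[0].weighted_expression <= queue[-1].weighted_expression

    def test_queue_subset_of_discordant(self, small_cohort):
        from tma_concord import apply_exclusions, classify_cases

        analysis, _ = apply_exclusions(small_cohort.cores, small_cohort.clinical)
        for marker, cases in classify_cases(analysis).items():
            queue = build_review_queue(cases)
            assert all(c.discordant for c in queue)
            ids = {c.case_id for c in cases}
            assert all(c.case_id in ids for c in queue)


class TestHeterogeneityTaxonomy:
    def test_neg_and_borderline_only(self):
        call = classify_heterogeneity(erpr_case([0.5, 5.0]))
        assert call.category == HeterogeneityCategory.NEG_AND_BORDERLINE_ONLY
        assert not call.strict_flag

    def test_neg_and_positive(self):
        call = classify_heterogeneity(erpr_case([0.5, 40.0]))
        assert call.category == HeterogeneityCategory.NEG_AND_POSITIVE

    def test_erpr_mixed_composition_counts_as_neg_and_positive(self):
        call = classify_heterogeneity(erpr_case([0.5, 5.0, 40.0]))
        assert call.category == HeterogeneityCategory.NEG_AND_POSITIVE

    @pytest.mark.parametrize(
        "profiles, category, strict",
        [
            ([(20, 5), (5, 30)], HeterogeneityCategory.EQUIV_AND_POS, False),
            ([(20, 5), (2, 3)], HeterogeneityCategory.NEG_AND_POS, True),
            ([(1, 2), (5, 30), (20, 5), (30, 5)], HeterogeneityCategory.NEG_EQUIV_POS, True),
        ],
    )
    def test_her2_compositions(self, profiles, category, strict):
        call = classify_heterogeneity(her2_case(profiles))
        assert call.category == category and call.strict_flag == strict

    def test_every_erpr_eligible_case_has_negative_core(self, small_cohort):
        from tma_concord import apply_exclusions, classify_cases

        analysis, _ = apply_exclusions(small_cohort.cores, small_cohort.clinical)
        for marker in (Marker.ER, Marker.PR):
            for case in build_review_queue(classify_cases(analysis)[marker]):
                assert any(s.erpr_tri == "negative" for s in case.core_statuses)

    def test_non_eligible_case_rejected(self):
        with pytest.raises(ValueError, match="not review-eligible"):
            classify_heterogeneity(erpr_case([5.0, 5.0]))


class TestSummaries:
    def _build_er_cohort(self):
        """1085 ER cases: 784 positive, 46 review-eligible, rest concordant."""
        cases, calls = [], []
        for i in range(46):  # discordant, case-positive
            c = erpr_case([0.5, 40.0], case=f"d{i:04d}")
            cases.append(c)
            if i < 16:
                calls.append(classify_heterogeneity(c))
        cases += [erpr_case([50.0, 60.0], case=f"p{i:04d}") for i in range(784 - 46)]
        cases += [erpr_case([0.1, 0.2], case=f"n{i:04d}") for i in range(1085 - 784)]
        return calls, cases

    def test_frequencies_with_both_denominators(self):
        calls, cases = self._build_er_cohort()
        s = summarize_heterogeneity(calls, cases)
        row = s[s.marker == "ER"].iloc[0]
        assert row.n_review_eligible == 46 and row.n_positive == 784
        assert row.pct_of_reviewed == pytest.approx(100 * 16 / 46)  # ~35 %
        assert row.pct_of_positive == pytest.approx(100 * 16 / 784)  # ~2 %

    def test_zero_confirmed_gives_zero_frequencies(self):
        _, cases = self._build_er_cohort()
        s = summarize_heterogeneity([], cases)
        row = s[s.marker == "ER"].iloc[0]
        assert row.n_confirmed == 0 and row.pct_of_reviewed == 0.0

    def test_her2_strict_count_bounded(self):
        cases = [
            her2_case([(20, 5), (5, 30)], case="a"),  # equiv&pos, not strict
            her2_case([(20, 5), (2, 3)], case="b"),  # neg&pos, strict
        ]
        calls = [classify_heterogeneity(c) for c in cases]
        s = summarize_heterogeneity(calls, cases)
        row = s[s.marker == "HER2"].iloc[0]
        assert row.n_confirmed_strict == 1 <= row.n_confirmed == 2
        assert row.pct_strict_of_positive == pytest.approx(50.0)

    def test_cross_marker_cooccurrence(self):
        calls = [
            classify_heterogeneity(erpr_case([0.5, 40], marker=Marker.PR, case="x")),
            classify_heterogeneity(her2_case([(20, 5), (2, 3)], case="x")),
            classify_heterogeneity(erpr_case([0.5, 40], case="y")),
        ]
        co = cross_marker_cooccurrence(calls)
        assert co.set_index("markers").n_cases["PR+HER2"] == 1
        assert co.set_index("markers").n_cases["ER+PR"] == 0
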