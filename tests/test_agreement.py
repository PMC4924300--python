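"""Contingency tables, Cohen's kappa (vs brute-force and statsmodels), and group tests."""

import numpy as np
import pytest
from scipy import stats

from tma_concord import (
    ClinicalRecord,
    ContingencyTable,
    CoreMeasurement,
    Marker,
    build_table,
    cellularity_comparison,
    cohens_kappa,
    collapse_case,
    core_number_association,
    stratified_agreement,
)
from tma_concord.agreement import JoinError


def table(counts, labels=None):
    counts = np.asarray(counts)
    labels = labels or (["negative", "positive"] if len(counts) == 2
                        else ["negative", "equivocal", "positive"])
    return ContingencyTable(labels=tuple(labels), counts=counts)


def kappa_brute_force(counts):
    """First-principles po/pe by explicit summation (independent oracle)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    po = sum(counts[i, i] for i in range(len(counts))) / n
    pe = 0.0
    for i in range(len(counts)):
        row = sum(counts[i, j] for j in range(len(counts)))
        col = sum(counts[j, i] for j in range(len(counts)))
        pe += row * col / n**2
    return (po - pe) / (1 - pe)


class TestCohensKappa:
    def test_perfect_diagonal(self):
        r = cohens_kappa(table([[50, 0], [0, 50]]))
        assert r.kappa == pytest.approx(1.0) and r.percent_agreement == 100.0

    def test_hand_computed_example(self):
        r = cohens_kappa(table([[25, 5], [5, 65]]))
        assert r.po == pytest.approx(0.90)
        assert r.pe == pytest.approx(0.58)
        assert r.kappa == pytest.approx(0.32 / 0.42, abs=5e-4)  # 0.762

    def test_independence_gives_zero(self):
        # cells equal products of margins / n
        r = cohens_kappa(table([[16, 24], [24, 36]]))
        assert r.kappa == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self):
        counts = np.array([[30, 5, 2], [4, 20, 6], [1, 3, 29]])
        perm = [2, 0, 1]
        r1 = cohens_kappa(table(counts))
        r2 = cohens_kappa(table(counts[np.ix_(perm, perm)]))
        assert r1.kappa == pytest.approx(r2.kappa)
        assert r1.kappa_se == pytest.approx(r2.kappa_se)

    def test_degenerate_table_flagged_not_raised(self):
        r = cohens_kappa(table([[10, 0], [0, 0]]))  # pe = 1
        assert r.undefined and np.isnan(r.kappa)
        r0 = cohens_kappa(table([[0, 0], [0, 0]]))
        assert r0.undefined

    def test_matches_statsmodels_kappa_and_ci(self):
        sm = pytest.importorskip("statsmodels.stats.inter_rater")
        for counts in ([[259, 42], [28, 756]], [[59, 14], [52, 44]],
                       [[864, 16, 28], [49, 2, 13], [17, 2, 94]]):
            ours = cohens_kappa(table(counts))
            ref = sm.cohens_kappa(np.asarray(counts))
            assert ours.kappa == pytest.approx(ref.kappa, abs=1e-10)
            assert ours.kappa_ci[0] == pytest.approx(ref.kappa_low, abs=1e-6)
            assert ours.kappa_ci[1] == pytest.approx(ref.kappa_upp, abs=1e-6)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = rng.choice([2, 3])
            counts = rng.integers(0, 50, size=(k, k))
            if counts.sum() == 0:
                continue
            r = cohens_kappa(table(counts))
            if not r.undefined:
                assert r.kappa == pytest.approx(kappa_brute_force(counts), abs=1e-12)


class TestBuildTable:
    def _cases(self):
        def er(case, pcts):
            return collapse_case([
                CoreMeasurement(case_id=case, core_id=f"k{i}", marker=Marker.ER,
                                percent_positive=p, tumor_nuclei=500)
                for i, p in enumerate(pcts)
            ])
        return [er("a", [50, 60]), er("b", [30, 40]), er("c", [20, 25])]

    def test_diagonal_table(self):
        clinical = [ClinicalRecord(c, "positive", "negative", "negative")
                    for c in ("a", "b", "c")]
        t = build_table(self._cases(), clinical, Marker.ER)
        assert t.counts.tolist() == [[0, 0], [0, 3]] and t.n == 3

    def test_unmatched_case_raises_join_error(self):
        clinical = [ClinicalRecord("a", "positive", "negative", "negative")]
        with pytest.raises(JoinError, match="b"):
            build_table(self._cases(), clinical, Marker.ER)

    def test_her2_equivocal_cell(self):
        case = collapse_case([
            CoreMeasurement(case_id="a", core_id=f"k{i}", marker=Marker.HER2,
                            pct_01=75.0, pct_2=20.0, pct_3=5.0, tumor_nuclei=500)
            for i in range(2)
        ])
        t = build_table([case], [ClinicalRecord("a", "positive", "positive", "negative")],
                        Marker.HER2)
        assert t.counts[1, 0] == 1  # central equivocal, clinical negative

    def test_stratified_partition_identity(self, small_cohort):
        from tma_concord import apply_exclusions, classify_cases

        analysis, _ = apply_exclusions(small_cohort.cores, small_cohort.clinical)
        classified = classify_cases(analysis)
        for marker, cases in classified.items():
            res = stratified_agreement(cases, small_cohort.clinical, marker)
            assert np.array_equal(
                res["concordant"].table.counts + res["discordant"].table.counts,
                res["all"].table.counts,
            )


class TestCellularityComparison:
    def test_identical_groups_p_near_one(self):
        x = [1000.0, 2000.0, 3000.0, 4000.0, 5000.0, 6000.0, 7000.0, 8000.0, 9000.0]
        r = cellularity_comparison(x, x)
        assert r.p_value > 0.95

    def test_exact_smallest_attainable_p(self):
        r = cellularity_comparison([1, 2, 3], [10, 20, 30])
        assert r.method == "exact" and r.p_value == pytest.approx(0.1)

    def test_shifted_groups_strongly_significant(self):
        rng = np.random.default_rng(3)
        conc = rng.lognormal(np.log(5225), 0.8, size=900)
        disc = rng.lognormal(np.log(3564), 0.8, size=100)
        r = cellularity_comparison(conc, disc)
        assert r.p_value < 0.001
        assert r.median_discordant < r.median_concordant

    def test_medians_and_iqrs_reported(self):
        r = cellularity_comparison([1, 2, 3, 4, 5], [10, 20, 30])
        assert r.median_concordant == 3 and r.median_discordant == 20
        assert r.iqr_concordant == (2, 4)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cellularity_comparison([], [1.0])


class TestCoreNumberAssociation:
    def test_equal_rates_statistic_near_zero(self):
        r = core_number_association(np.array([[90, 10], [180, 20], [270, 30]]))
        assert r.statistic == pytest.approx(0.0, abs=1e-12) and r.df == 2

    def test_from_flags_matches_scipy(self):
        ks = [2] * 20 + [3] * 30 + [4] * 50
        rng = np.random.default_rng(1)
        flags = list(rng.random(100) < 0.2)
        r = core_number_association(core_numbers=ks, discordant=flags)
        chi2, p, _, _ = stats.chi2_contingency(r.table.to_numpy(), correction=False)
        assert r.statistic == pytest.approx(chi2) and r.p_value == pytest.approx(p)

    def test_zero_margin_row_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            r = core_number_association(np.array([[0, 0], [20, 5], [30, 10]]))
        assert r.df == 1
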