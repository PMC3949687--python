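"""Cohort summaries, Welch's t and the exact permutation oracle."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import integrate, stats

from usherdx.models import AnnotatedVariant, PatientCase, VariantCall
from usherdx.report import (
    compare_onset_by_modifier,
    exact_permutation_pvalue,
    percent,
    summarize_cohort,
    welch_t_test,
)
from usherdx.diagnosis import diagnose_cohort

MODIFIER_ONSETS = [5.0, 5.0, 6.0]
COMPARISON_ONSETS = [13.0, 6.0, 12.0, 8.0, 13.0, 10.0]


class TestPercentRendering:
    @pytest.mark.parametrize(
        "n, d, expected",
        [(16, 17, 94.1), (7, 17, 41.2), (3, 17, 17.6), (2, 17, 11.8), (1, 1, 100.0),
         (1, 8, 12.5)],
    )
    def test_half_away_from_zero_to_one_decimal(self, n, d, expected):
        assert percent(n, d) == expected

    def test_empty_denominator(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)


class TestWelch:
    def test_statistic_df_and_p_against_library_implementation(self):
        t, df, p = welch_t_test(MODIFIER_ONSETS, COMPARISON_ONSETS)
        ref = stats.ttest_ind(MODIFIER_ONSETS, COMPARISON_ONSETS, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert df == pytest.approx(ref.df)
        assert p == pytest.approx(ref.pvalue)

    def test_p_against_numerical_integration_of_t_density(self):
        """Two-sided p recomputed by integrating the t density directly."""
        t, df, p = welch_t_test(MODIFIER_ONSETS, COMPARISON_ONSETS)

        def t_pdf(x):
            c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
            return c * (1 + x * x / df) ** (-(df + 1) / 2)

        tail, _ = integrate.quad(t_pdf, abs(t), np.inf)
        assert p == pytest.approx(2 * tail, rel=1e-8)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [2.0, 3.0])

    def test_symmetry(self):
        t1, df1, p1 = welch_t_test(MODIFIER_ONSETS, COMPARISON_ONSETS)
        t2, df2, p2 = welch_t_test(COMPARISON_ONSETS, MODIFIER_ONSETS)
        assert (df1, p1) == pytest.approx((df2, p2))
        assert t1 == pytest.approx(-t2)


class TestExactPermutation:
    def test_against_independent_enumeration(self):
        p, n = exact_permutation_pvalue(MODIFIER_ONSETS, COMPARISON_ONSETS)
        assert n == math.comb(9, 3) == 84
        # brute-force oracle written out in full
        pool = MODIFIER_ONSETS + COMPARISON_ONSETS
        observed = abs(np.mean(MODIFIER_ONSETS) - np.mean(COMPARISON_ONSETS))
        count = 0
        for idx in combinations(range(9), 3):
            a = [pool[i] for i in idx]
            b = [pool[i] for i in range(9) if i not in idx]
            if abs(np.mean(a) - np.mean(b)) >= observed - 1e-12:
                count += 1
        assert p == pytest.approx(count / 84)
        assert p == pytest.approx(4 / 84)

    def test_identical_groups_give_p_one(self):
        p, _ = exact_permutation_pvalue([5.0, 5.0], [5.0, 5.0])
        assert p == 1.0

    def test_label_invariance_and_lower_bound(self):
        p_ab, n = exact_permutation_pvalue(MODIFIER_ONSETS, COMPARISON_ONSETS)
        p_ba, _ = exact_permutation_pvalue(COMPARISON_ONSETS, MODIFIER_ONSETS)
        assert p_ab == pytest.approx(p_ba)
        assert p_ab >= 1 / n


class TestOnsetComparison:
    def test_groups_are_the_printed_case_lists(self, fixture_result):
        oc = fixture_result.onset_comparison
        assert sorted(oc.modifier_onsets) == MODIFIER_ONSETS
        assert sorted(oc.comparison_onsets) == sorted(COMPARISON_ONSETS)

    def test_unknown_onset_patients_excluded(self, fixture_result):
        # cases 2, 15, 17 have modifier/biallelic status but unknown onset
        oc = fixture_result.onset_comparison
        assert len(oc.modifier_onsets) + len(oc.comparison_onsets) == 9

    def test_digenic_patient_joins_comparison_group_on_request(self, fixture_result):
        oc = compare_onset_by_modifier(
            fixture_result.cases, fixture_result.diagnoses, include_digenic=True
        )
        assert sorted(oc.comparison_onsets) == sorted(COMPARISON_ONSETS + [10.0])


def _solved_patient(pid="p1"):
    call = VariantCall(patient_id=pid, gene="MYO7A", hgvs_c="c.100C>T",
                       depth=300, mean_base_quality=30.0, alt_fraction=0.99)
    v = AnnotatedVariant(call=call, zygosity="hom", consequence="nonsense",
                         tier="pathogenic")
    return PatientCase(patient_id=pid, variants=[v])


class TestSummarize:
    def test_single_solved_patient_is_full_yield(self):
        case = _solved_patient()
        summary = summarize_cohort(diagnose_cohort([case]), [case])
        assert summary.yield_percent == 100.0
        assert summary.per_gene_biallelic_counts == {"MYO7A": 1}
        assert summary.n_two_pathogenic == 1

    def test_stable_under_patient_reordering(self, fixture_result):
        forward = summarize_cohort(fixture_result.diagnoses, fixture_result.cases)
        backward = summarize_cohort(
            list(reversed(fixture_result.diagnoses)),
            list(reversed(fixture_result.cases)),
        )
        assert forward.to_dict() == backward.to_dict()

    def test_empty_cohort_rejected(self):
        from usherdx.models import UsherdxError

        with pytest.raises(UsherdxError):
            summarize_cohort([], [])
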