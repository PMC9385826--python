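"""Agreement proportions, Wilson intervals, 2x2 odds ratios, sample size.

The regression constants below are numerator/denominator pairs and
whole-percent confidence intervals, and 2x2 contingency cells with their
odds ratios, from published attitude tables for a scenario-based
prognosis tool; they pin the implementation to real reported output.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from threescenarios.associations import (
    association_from_levels,
    age_band,
    collapse_agreement,
    est_band,
    format_or,
    odds_ratio_2x2,
    required_sample_size,
    variable_association,
    wilson_interval,
)
from tests.conftest import make_record

# (numerator, denominator, printed low %, printed high %) — Wilson agrees
# exactly after rounding on all of these rows
WILSON_EXACT_ROWS = [
    (126, 138, 85, 95), (136, 142, 91, 98), (126, 144, 81, 92),
    (78, 140, 47, 64), (89, 139, 56, 72), (122, 138, 82, 93),
    (41, 138, 23, 38), (58, 140, 34, 50), (107, 142, 68, 82),
    (127, 141, 84, 94), (131, 142, 87, 96), (122, 142, 79, 91),
    (115, 142, 74, 87), (110, 141, 70, 84), (28, 143, 14, 27),
    (14, 143, 6, 16), (52, 143, 29, 45), (44, 142, 24, 39),
    (66, 142, 38, 55), (32, 142, 16, 30), (127, 140, 85, 94),
    (92, 101, 84, 95), (51, 100, 41, 61), (97, 101, 90, 98),
    (71, 99, 62, 80), (56, 101, 46, 65), (85, 100, 77, 91),
    (9, 99, 5, 16), (47, 98, 38, 58), (115, 137, 77, 89),
    (98, 134, 65, 80), (51, 135, 30, 46), (122, 135, 84, 94),
    (98, 138, 63, 78), (103, 136, 68, 82), (214, 222, 93, 98),
    (17, 222, 5, 12), (26, 222, 8, 17), (42, 222, 14, 25),
    (19, 222, 6, 13), (207, 222, 89, 96), (196, 222, 83, 92),
    (113, 222, 44, 57), (36, 222, 12, 22), (6, 222, 1, 6),
    (193, 222, 82, 91),
]

# rows whose printed upper bound sits 1 point above the Wilson value
# (no standard interval reproduces them without breaking other rows)
WILSON_OFF_BY_ONE_ROWS = [
    (49, 143, 27, 43), (37, 131, 21, 37), (117, 133, 81, 93),
]

# (cells a, b, c, d; printed OR, CI, two-decimal p) with
# a/b = exposed agree/disagree, c/d = reference agree/disagree
CONTINGENCY_ROWS = {
    "hope_above_median": ((66, 2, 58, 10), "5.7 (1.2-27)", 0.03),
    "sex_male": ((82, 10, 44, 2), "0.37 (0.08-1.8)", 0.22),
    "education_high": ((71, 5, 49, 6), "1.7 (0.50-6.0)", 0.38),
    "time_dx_gt8w": ((79, 9, 47, 3), "0.56 (0.14-2.2)", 0.40),
    "lotr_above_median": ((77, 7, 46, 5), "1.2 (0.36-4.0)", 0.77),
    "age_50_70": ((63, 7, 14, 2), "1.3 (0.24-6.9)", None),
    "age_over_70": ((49, 3, 14, 2), "2.3 (0.35-15)", None),
    "est_9_15": ((37, 5, 44, 4), "0.67 (0.17-2.7)", None),
    "cancer_prostate": ((18, 1, 32, 4), "2.3 (0.23-22)", None),
    "cancer_kidney": ((12, 1, 32, 4), "1.5 (0.15-15)", None),
    "cancer_nsclc": ((19, 2, 32, 4), "1.2 (0.20-7.1)", None),
    "cancer_pancreatic": ((16, 2, 32, 4), "1.0 (0.17-6.1)", None),
}

# rows where one published CI bound differs from the Wald closed form in
# its final digit (consistent with profile-likelihood intervals having
# been used for those bounds): cells, Wald display, published display, p
CONTINGENCY_LAST_DIGIT_ROWS = {
    "stai_above_median": ((64, 6, 60, 5), "0.89 (0.26-3.1)",
                          "0.89 (0.25-3.1)", 0.85),
    "est_over_15": ((45, 3, 44, 4), "1.4 (0.29-6.4)",
                    "1.4 (0.29-6.5)", None),
}


class TestCollapseAgreement:
    def test_mixed_responses(self):
        assert collapse_agreement(
            ["agree", "strongly_agree", "unsure", "disagree", None]
        ) == (2, 4)

    def test_all_missing_degenerate(self):
        assert collapse_agreement([None, "", "missing"]) == (0, 0)

    def test_high_agreement_cohort(self):
        responses = (["strongly_agree"] * 60 + ["agree"] * 66
                     + ["unsure"] * 7 + ["disagree"] * 3
                     + ["strongly_disagree"] * 2 + [None] * 8)
        assert collapse_agreement(responses) == (126, 138)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="invalid Likert"):
            collapse_agreement(["yes"])


class TestWilsonInterval:
    @pytest.mark.parametrize("x,n,lo,hi", WILSON_EXACT_ROWS)
    def test_reproduces_printed_intervals(self, x, n, lo, hi):
        l, h = wilson_interval(x, n)
        assert (round(100 * l), round(100 * h)) == (lo, hi)

    @pytest.mark.parametrize("x,n,lo,hi", WILSON_OFF_BY_ONE_ROWS)
    def test_known_one_point_discrepancies(self, x, n, lo, hi):
        l, h = wilson_interval(x, n)
        assert round(100 * l) == lo
        assert abs(round(100 * h) - hi) <= 1

    def test_zero_successes_boundary_is_exact(self):
        lo, hi = wilson_interval(0, 10)
        assert lo == 0.0
        assert 0 < hi < 1

    @given(x=st.integers(0, 50), n=st.integers(1, 50))
    def test_complement_symmetry(self, x, n):
        x = min(x, n)
        lo, hi = wilson_interval(x, n)
        lo_c, hi_c = wilson_interval(n - x, n)
        assert lo == pytest.approx(1 - hi_c, abs=1e-12)
        assert hi == pytest.approx(1 - lo_c, abs=1e-12)

    def test_zero_denominator_flagged(self):
        with pytest.raises(ValueError, match="zero denominator"):
            wilson_interval(0, 0)


class TestOddsRatio2x2:
    @pytest.mark.parametrize(
        "cells,display,p", list(CONTINGENCY_ROWS.values()),
        ids=list(CONTINGENCY_ROWS))
    def test_reproduces_printed_rows(self, cells, display, p):
        r = odds_ratio_2x2(*cells)
        assert format_or(r) == display
        if p is not None:
            assert round(r.p_value, 2) == p

    @pytest.mark.parametrize(
        "cells,wald,published,p", list(CONTINGENCY_LAST_DIGIT_ROWS.values()),
        ids=list(CONTINGENCY_LAST_DIGIT_ROWS))
    def test_last_digit_discrepancy_rows(self, cells, wald, published, p):
        """The Wald closed form matches the published OR and p exactly
        and each CI bound to within one unit in the last printed digit."""
        r = odds_ratio_2x2(*cells)
        assert format_or(r) == wald
        assert format_or(r).split(" ")[0] == published.split(" ")[0]
        if p is not None:
            assert round(r.p_value, 2) == p

    def test_zero_cell_gives_na(self):
        r = odds_ratio_2x2(13, 0, 32, 4)
        assert r.odds_ratio is None and r.ci_low is None \
            and r.p_value is None
        assert format_or(r) == "NA"

    def test_identical_rows_give_unit_or(self):
        assert odds_ratio_2x2(30, 7, 30, 7).odds_ratio == 1.0

    @given(a=st.integers(1, 80), b=st.integers(1, 80),
           c=st.integers(1, 80), d=st.integers(1, 80))
    def test_swapping_rows_inverts_and_double_swap_preserves(self, a, b, c, d):
        base = odds_ratio_2x2(a, b, c, d).odds_ratio
        swapped = odds_ratio_2x2(c, d, a, b).odds_ratio
        both = odds_ratio_2x2(b, a, d, c).odds_ratio
        assert swapped == pytest.approx(1 / base, rel=1e-12)
        assert both == pytest.approx(1 / base, rel=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(-1, 2, 3, 4)


class TestVariableAssociation:
    def test_multilevel_overall_p_matches_printed_values(self):
        """The per-variable p for multi-level covariates is the
        likelihood-ratio test of independence; it reproduces the printed
        two-decimal values for the three multi-level variables."""
        age = [("<50", 14, 2), ("50-70", 63, 7), (">70", 49, 3)]
        cancer = [("other", 32, 4), ("prostate", 18, 1), ("kidney", 12, 1),
                  ("nsclc", 19, 2), ("pancreatic", 16, 2),
                  ("colorectal", 16, 2), ("breast", 13, 0)]
        est = [("<9", 44, 4), ("9-15", 37, 5), (">15", 45, 3)]
        for table, ref, printed in [(age, "<50", 0.60),
                                    (cancer, "other", 0.78),
                                    (est, "<9", 0.64)]:
            levels, responses = [], []
            for lv, agree, disagree in table:
                levels += [lv] * (agree + disagree)
                responses += [True] * agree + [False] * disagree
            va = association_from_levels(levels, responses, reference=ref)
            assert round(va.overall_p, 2) == printed

    def test_two_level_covariate_reduces_to_2x2(self):
        levels = ["m"] * 92 + ["f"] * 46
        responses = [True] * 82 + [False] * 10 + [True] * 44 + [False] * 2
        va = association_from_levels(levels, responses, reference="f")
        direct = odds_ratio_2x2(82, 10, 44, 2)
        assert va.results[0].odds_ratio == pytest.approx(direct.odds_ratio)
        assert va.results[0].p_value == pytest.approx(direct.p_value)

    def test_reference_level_absent_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            association_from_levels(["a", "b"], [True, False],
                                    reference="zzz")

    def test_cohort_field_and_derived_bands(self):
        records = []
        for i, (age, est, sex, resp) in enumerate([
                (45, 5, "male", "agree"), (60, 12, "female", "agree"),
                (80, 20, "male", "disagree"), (66, 10, "female", "agree"),
                (49, 6, "male", "unsure"), (75, 30, "female", "agree")]):
            records.append(make_record(
                f"P{i}", est=float(est), age_years=age, sex=sex,
                likert_responses={"helpful": resp}))
        va = variable_association(records, "sex", "helpful")
        assert va.reference_label == "female"
        va_age = variable_association(records, "age_band", "helpful")
        assert {r.exposure_label for r in va_age.results} <= {"50-70", ">70"}

    def test_age_and_est_band_edges(self):
        assert age_band(49) == "<50" and age_band(50) == "50-70"
        assert age_band(70) == "50-70" and age_band(71) == ">70"
        assert est_band(8.9) == "<9 months"
        assert est_band(9) == "9-15 months"
        assert est_band(15) == "9-15 months"
        assert est_band(15.1) == ">15 months"


class TestRequiredSampleSize:
    def test_design_case_lands_near_seventy(self):
        n = required_sample_size(0.60, 0.80, power=0.95, alpha=0.05,
                                 attrition=0.20)
        assert n == 68  # independent normal-approximation hand computation
        assert 60 <= n <= 80

    def test_attrition_inflation_definition(self):
        base = required_sample_size(0.60, 0.80, power=0.95, alpha=0.05)
        infl = required_sample_size(0.60, 0.80, power=0.95, alpha=0.05,
                                    attrition=0.20)
        assert infl == math.ceil(base / 0.8)

    def test_grows_without_bound_as_proportions_approach(self):
        sizes = [required_sample_size(0.7 - eps, 0.7, power=0.5)
                 for eps in (0.2, 0.1, 0.05, 0.01)]
        assert sizes == sorted(sizes) and sizes[-1] > 1000

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            required_sample_size(0.8, 0.6)
        with pytest.raises(ValueError):
            required_sample_size(0.6, 0.8, attrition=1.0)
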