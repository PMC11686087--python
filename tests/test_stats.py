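"""Cohort statistics tests: test selection, Cox screen, variability, power."""

import numpy as np
import pandas as pd
import pytest

from pwavekit.stats import (
    CohortAnalysis,
    between_group_change_test,
    cox_screen_and_fit,
    intraobserver_variability,
    paired_change_test,
    posthoc_power,
)
from pwavekit.synth import SynthCohortSpec, generate_cohort


class TestPairedChange:
    def test_identical_passes_are_degenerate(self):
        pre = np.array([100.0, 110.0, 120.0, 130.0])
        res = paired_change_test(pre, pre)
        assert res.mean_change == 0.0
        assert res.p_value == 1.0
        assert res.test == "degenerate"

    def test_detects_a_real_shift(self, rng):
        pre = rng.normal(139.0, 10.0, 50)
        post = pre + rng.normal(7.0, 3.0, 50)
        res = paired_change_test(pre, post)
        assert res.mean_change == pytest.approx(7.0, abs=1.5)
        assert res.p_value < 1e-6

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 paired"):
            paired_change_test([1.0, 2.0], [1.5, 2.5])

    def test_nonnormal_changes_use_rank_test(self, rng):
        pre = np.zeros(40)
        post = rng.exponential(2.0, 40) ** 3  # heavily skewed changes
        res = paired_change_test(pre, post)
        assert res.test == "wilcoxon"


class TestBetweenGroup:
    def test_label_swap_negates_difference(self, rng):
        a = rng.normal(0.0, 1.0, 40)
        b = rng.normal(5.0, 1.0, 40)
        r1 = between_group_change_test(a, b)
        r2 = between_group_change_test(b, a)
        assert r1.difference == pytest.approx(-r2.difference)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_separated_groups_are_significant(self, rng):
        ok = 0
        for _ in range(10):
            a = rng.normal(0.0, 1.0, 130)
            b = rng.normal(5.0, 1.0, 50)
            if between_group_change_test(a, b).p_value < 0.001:
                ok += 1
        assert ok == 10

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            between_group_change_test([], [1.0, 2.0, 3.0])


class TestCoxScreen:
    def test_null_covariate_hr_near_one(self):
        spec = SynthCohortSpec(n_success=1500, n_failure=500,
                               log_hr_pwdc_change=0.0, log_hr_pwa_change=0.0, seed=21)
        coh = generate_cohort(spec)
        uni, _ = cox_screen_and_fit(coh, ["age_years"])
        hr = uni.hr.iloc[0]
        assert 0.9 < hr < 1.1

    def test_screen_rule_structure(self):
        coh = generate_cohort(SynthCohortSpec(seed=22))
        covs = ["pwdc_change_z", "pwa_change_z", "age_years", "male", "bmi"]
        uni, multi = cox_screen_and_fit(coh, covs, threshold=0.05)
        selected = set(uni.loc[uni.p < 0.05, "term"])
        assert set(multi.term) == selected
        assert (uni.stage == "univariable").all()
        if len(multi):
            assert (multi.stage == "multivariable").all()
            assert (multi.ci_low <= multi.hr).all() and (multi.hr <= multi.ci_high).all()

    def test_too_few_events_rejected(self):
        coh = generate_cohort(SynthCohortSpec(seed=23)).head(20)
        coh = coh.assign(event=0)
        with pytest.raises(ValueError, match="10 events"):
            cox_screen_and_fit(coh, ["age_years"])

    def test_constant_covariate_named(self):
        coh = generate_cohort(SynthCohortSpec(seed=24))
        coh["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            cox_screen_and_fit(coh, ["flat"])


class TestVariability:
    def test_identical_passes_give_zero(self):
        df = pd.DataFrame({"pwd_ms": [100.0, 110.0], "pwa_mv": [0.1, 0.2]})
        rep = intraobserver_variability(df, df.copy())
        assert (rep.mean_abs_diff == 0.0).all()
        assert (rep.sd_abs_diff == 0.0).all()
        assert (rep.percent_variability == 0.0).all()

    def test_uniform_two_ms_shift(self):
        p1 = pd.DataFrame({"pwd_ms": [99.0, 100.0, 101.0]})
        p2 = p1 + 2.0
        rep = intraobserver_variability(p1, p2)
        assert rep.mean_abs_diff.iloc[0] == pytest.approx(2.0)
        assert rep.sd_abs_diff.iloc[0] == pytest.approx(0.0)
        # grand mean is 101 ms across both passes
        assert rep.percent_variability.iloc[0] == pytest.approx(2.0 / 101.0 * 100.0)

    def test_mismatched_records_rejected(self):
        p1 = pd.DataFrame({"pwd_ms": [1.0, 2.0]}, index=["a", "b"])
        p2 = pd.DataFrame({"pwd_ms": [1.0, 2.0]}, index=["a", "c"])
        with pytest.raises(ValueError, match="mismatched"):
            intraobserver_variability(p1, p2)


class TestPower:
    def test_zero_effect_power_equals_alpha(self):
        assert posthoc_power(50, 50, 0.0, alpha=0.05) == pytest.approx(0.05, abs=1e-6)

    def test_classical_table_value(self):
        # n = 64/group at d = 0.5 is the textbook 80% design
        assert posthoc_power(64, 64, 0.5) == pytest.approx(0.80, abs=0.01)

    def test_monotone_in_effect_and_n(self):
        assert posthoc_power(40, 40, 0.6) > posthoc_power(40, 40, 0.4)
        assert posthoc_power(80, 80, 0.5) > posthoc_power(40, 40, 0.5)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            posthoc_power(40, 40, 0.5, alpha=1.5)


class TestCohortAnalysisModel:
    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="pwdc_ms_pre"):
            CohortAnalysis.from_dataframe(pd.DataFrame({"x": [1.0]}))

    def test_fit_produces_all_tables_and_summary(self):
        coh = generate_cohort(SynthCohortSpec(seed=30))
        model = CohortAnalysis.from_dataframe(
            coh, covariates=["pwdc_change_z", "pwa_change_z", "age_years"]
        )
        res = model.fit()
        assert len(res.paired) == 8  # 4 parameters x 2 groups
        assert len(res.between) == 4
        assert set(res.cox_univariable.term) == {"pwdc_change_z", "pwa_change_z", "age_years"}
        text = res.summary()
        assert "Paired pre/post comparisons" in text
        assert "Cox regression" in text

    def test_designed_failure_arm_shows_pwdc_increase(self):
        coh = generate_cohort(SynthCohortSpec(seed=31))
        res = CohortAnalysis.from_dataframe(coh, group_col="group").fit()
        row = res.paired[(res.paired.parameter == "pwdc_ms")
                         & (res.paired.group == "failure")].iloc[0]
        assert row.mean_change == pytest.approx(7.0, abs=3.0)
        assert row.p < 0.001
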