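"""Statistical tests against independent oracles, plus end-to-end patterns."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from respira import (
    DegenerateDataError,
    ValidationError,
    evaluate_clogging,
    evaluate_fitting,
    one_way_anova,
    paired_t_two_sided,
    shapiro_wilk,
    tukey_hsd,
)


class TestShapiroWilk:
    def test_normal_samples_rarely_rejected(self):
        rng = np.random.default_rng(42)
        accepted = sum(
            shapiro_wilk(rng.normal(size=10))[1] > 0.05 for _ in range(100)
        )
        assert accepted >= 90

    def test_lognormal_samples_usually_rejected(self):
        rng = np.random.default_rng(43)
        rejected = sum(
            shapiro_wilk(rng.lognormal(0.0, 1.0, 50))[1] < 0.05 for _ in range(100)
        )
        assert rejected >= 80

    def test_constant_sample_raises(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk(np.full(10, 2.0))

    def test_sample_size_limits(self):
        with pytest.raises(ValidationError):
            shapiro_wilk([1.0, 2.0])

    def test_matches_reference_r_implementation(self):
        """W and p agree with R's shapiro.test to 1e-8."""
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 20)
        w, p = shapiro_wilk(x)
        vec = ",".join("%.17g" % v for v in x)
        res = subprocess.run(
            ["Rscript", "-e",
             f"x<-c({vec}); r<-shapiro.test(x);"
             " cat(sprintf('%.12g %.12g', r$statistic, r$p.value))"],
            capture_output=True, text=True, check=True,
        )
        rw, rp_ = map(float, res.stdout.split())
        assert w == pytest.approx(rw, abs=1e-8)
        assert p == pytest.approx(rp_, abs=1e-8)


class TestPairedT:
    def test_symmetric_differences_give_zero_t(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        res = paired_t_two_sided(a, np.zeros(4))
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_ten_subjects_have_nine_degrees_of_freedom(self, rng):
        res = paired_t_two_sided(rng.normal(size=10), rng.normal(size=10))
        assert res.df == 9

    def test_matches_closed_form_oracle(self, rng):
        a = rng.normal(1.0, 1.0, 8)
        b = rng.normal(0.5, 1.0, 8)
        res = paired_t_two_sided(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(8))
        p = 2 * stats.t.sf(abs(t), 7)
        assert res.t_stat == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_zero_variance_differences_raise(self):
        with pytest.raises(DegenerateDataError):
            paired_t_two_sided([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.f_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_six_groups_have_five_df_between(self, rng):
        groups = [rng.normal(size=10) for _ in range(6)]
        res = one_way_anova(groups)
        assert res.df_between == 5
        assert res.df_within == 54

    def test_matches_brute_force_sums_oracle(self, rng):
        groups = [rng.normal(i, 1.0, 5) for i in range(3)]
        res = one_way_anova(groups)
        pooled = np.concatenate(groups)
        grand = pooled.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f = (ss_between / 2) / (ss_within / 12)
        p = stats.f.sf(f, 2, 12)
        assert res.f_stat == pytest.approx(f, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValidationError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValidationError):
            one_way_anova([[1.0], [2.0, 3.0]])
        with pytest.raises(DegenerateDataError):
            one_way_anova([[1.0, 1.0], [2.0, 2.0]])


class TestTukey:
    def test_two_group_case_equals_pooled_t_test(self, rng):
        """With two groups, the studentized range gives q = sqrt(2)|t|."""
        groups = [rng.normal(0, 1, 8), rng.normal(0.7, 1, 8)]
        tm = tukey_hsd(groups)
        t_p = stats.ttest_ind(*groups, equal_var=True).pvalue
        assert tm.p_values[0, 1] == pytest.approx(t_p, abs=1e-6)

    def test_matches_statsmodels_on_three_groups(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = [rng.normal(0.5 * i, 1.0, 5) for i in range(3)]
        tm = tukey_hsd(groups, labels=["a", "b", "c"])
        sm = pairwise_tukeyhsd(
            np.concatenate(groups), np.repeat(["a", "b", "c"], 5)
        )
        ours = [tm.p("a", "b"), tm.p("a", "c"), tm.p("b", "c")]
        np.testing.assert_allclose(ours, sm.pvalues, atol=1e-8)

    def test_matrix_symmetric_with_unit_diagonal(self, rng):
        tm = tukey_hsd([rng.normal(size=6) for _ in range(4)])
        np.testing.assert_array_equal(tm.p_values, tm.p_values.T)
        np.testing.assert_array_equal(np.diag(tm.p_values), 1.0)

    def test_null_groups_rarely_separable(self):
        rng = np.random.default_rng(44)
        clean = 0
        for _ in range(100):
            tm = tukey_hsd([rng.normal(size=10) for _ in range(4)])
            off = tm.p_values[~np.eye(4, dtype=bool)]
            clean += off.min() > 0.05
        assert clean >= 90

    def test_clip_legacy_saturates_off_diagonal(self, rng):
        groups = [rng.normal(3 * i, 0.5, 6) for i in range(3)]
        tm = tukey_hsd(groups, clip_legacy=True)
        off = tm.p_values[~np.eye(3, dtype=bool)]
        assert off.min() >= 0.001
        assert off.max() <= 0.900


def _aggregate_like(rows):
    return pd.DataFrame(rows, columns=["subject_id", "channel", "kind", "clog_pct",
                                       "p2p", "n_cycles"])


class TestEvaluateFitting:
    def test_pressure_and_humidity_separate_loose_but_temperature_does_not(
        self, fitting_table
    ):
        rep = evaluate_fitting(fitting_table)
        for ch in ("p", "rh"):
            sig = rep.channels[ch].significant
            assert sig["fit_initial~fit_loose"], ch
            assert sig["fit_loose~fit_final"], ch
        assert not any(rep.channels["t_c"].significant.values())

    def test_pressure_recovers_initial_distribution_after_refit(self, fitting_table):
        rep = evaluate_fitting(fitting_table)
        assert not rep.channels["p"].significant["fit_initial~fit_final"]

    def test_all_tests_have_nine_df(self, fitting_table):
        rep = evaluate_fitting(fitting_table)
        for ch in rep.channels.values():
            assert all(t.df == 9 for t in ch.tests)

    def test_identical_conditions_with_jitter_not_significant(self):
        rng = np.random.default_rng(5)
        rows = []
        for s in range(1, 11):
            base = rng.uniform(0.5, 1.5)
            for kind in ("fit_initial", "fit_loose", "fit_final"):
                rows.append([f"S{s:02d}", "p", kind, None,
                             base + rng.normal(0, 1e-6), 50])
        rep = evaluate_fitting(_aggregate_like(rows))
        assert not any(rep.channels["p"].significant.values())


class TestEvaluateClogging:
    def test_pressure_significant_humidity_and_temperature_not(self, clogging_table):
        rep = evaluate_clogging(clogging_table)
        assert rep.channels["p"].significant
        assert not rep.channels["rh"].significant
        assert not rep.channels["t_c"].significant

    def test_pressure_excludes_full_clog_by_default(self, clogging_table):
        rep = evaluate_clogging(clogging_table)
        assert rep.channels["p"].excluded_levels == (100,)
        assert rep.channels["p"].anova.df_between == 4
        assert rep.channels["rh"].anova.df_between == 5

    def test_pressure_tukey_separates_eighty_percent_only(self, clogging_table):
        tk = evaluate_clogging(clogging_table).channels["p"].tukey
        assert tk.labels == (0, 20, 40, 60, 80)
        for lv in (0, 20, 40, 60):
            assert tk.p(80, lv) < 0.05
        for a in (0, 20, 40, 60):
            for b in (0, 20, 40, 60):
                if a != b:
                    assert tk.p(a, b) > 0.05

    def test_airflow_separates_full_clog_from_all_others(self, clogging_table):
        res = evaluate_clogging(clogging_table).channels["af"]
        assert res.significant
        for lv in (0, 20, 40, 60, 80):
            assert res.tukey.p(100, lv) < 0.05

    def test_exclusion_leaving_one_level_raises(self, clogging_table):
        with pytest.raises(ValidationError):
            evaluate_clogging(
                clogging_table,
                exclude_levels_for={"p": (0, 20, 40, 60, 80)},
            )
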