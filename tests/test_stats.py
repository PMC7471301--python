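import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st

from orbimetry import (
    StudySpec,
    bland_altman,
    bonferroni_pairwise,
    cronbach_alpha,
    generate_study,
    icc,
    method_summary,
    paired_t,
    pearson_r,
    rm_anova_oneway,
)
from orbimetry.stats import MeasurementTable


@pytest.fixture(scope="module")
def random_matrix():
    rng = np.random.default_rng(0)
    return rng.normal(18.0, 3.0, size=(15, 3)) + np.array([0.0, 1.4, 0.8])


class TestRmAnova:
    def test_identical_columns_give_f_zero(self):
        m = np.tile(np.arange(10.0)[:, None], (1, 3))
        res = rm_anova_oneway(m)
        assert res.F == 0.0 and res.p == 1.0

    def test_f_equals_squared_paired_t_at_two_conditions(self):
        """At k = 2 the RM-ANOVA F statistic is the square of the paired t,
        with the same p-value."""
        rng = np.random.default_rng(1)
        m = rng.normal(0, 1, size=(20, 2))
        res = rm_anova_oneway(m)
        tt = paired_t(m[:, 0], m[:, 1])
        assert res.F == pytest.approx(tt.t**2, rel=1e-10)
        assert res.p == pytest.approx(tt.p, rel=1e-10)

    def test_matches_hand_sums_of_squares(self):
        """3x3 worked matrix against an explicit sums-of-squares
        decomposition."""
        m = np.array([[1.0, 2.0, 4.0], [2.0, 3.0, 3.0], [3.0, 5.0, 7.0]])
        grand = m.mean()
        ss_cond = 3 * sum((m[:, j].mean() - grand) ** 2 for j in range(3))
        ss_subj = 3 * sum((m[i].mean() - grand) ** 2 for i in range(3))
        ss_err = ((m - grand) ** 2).sum() - ss_cond - ss_subj
        f_expect = (ss_cond / 2) / (ss_err / 4)
        res = rm_anova_oneway(m)
        assert res.F == pytest.approx(f_expect, rel=1e-12)
        assert (res.df_num, res.df_den) == (2, 4)

    def test_matches_pingouin(self, random_matrix):
        res = rm_anova_oneway(random_matrix)
        df = (
            pd.DataFrame(random_matrix, columns=list("ABC"))
            .reset_index()
            .melt(id_vars="index")
        )
        aov = pg.rm_anova(data=df, dv="value", within="variable", subject="index")
        assert res.F == pytest.approx(float(aov["F"][0]), rel=1e-9)
        assert res.p == pytest.approx(float(aov["p_unc"][0]), rel=1e-9)

    def test_degenerate_zero_error_variance(self):
        m = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])  # constant shift
        res = rm_anova_oneway(m)
        assert np.isinf(res.F) and res.p == 0.0 and res.degenerate

    def test_incomplete_matrix_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="complete"):
            rm_anova_oneway(m)


class TestPairedT:
    def test_equal_vectors(self):
        r = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0

    def test_closed_form_d123(self):
        """d = (1,2,3): t = 2 / (1/sqrt(3)) = 3.4641, df = 2."""
        r = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-10)
        assert r.df == 2

    def test_constant_nonzero_difference_degenerate(self):
        r = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert r.degenerate and r.p == 0.0 and np.isinf(r.t)

    def test_type_i_error_rate_under_null(self):
        """At alpha = 0.05 the null rejection rate over 2000 simulated
        datasets stays within binomial tolerance of 0.05."""
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(2000):
            d = rng.normal(0, 1, 200)
            if paired_t(d, np.zeros_like(d)).p < 0.05:
                rejections += 1
        assert abs(rejections / 2000 - 0.05) < 0.015


class TestBonferroni:
    def test_pair_count_and_cap(self, random_matrix):
        out = bonferroni_pairwise(random_matrix)
        assert len(out) == 3
        for raw, adj, _ in out.values():
            assert adj == min(1.0, raw * 3)
            assert adj >= raw

    def test_shifted_method_detected(self):
        """With one clearly shifted column only its two pairs are
        significant, matching direct per-pair t-tests."""
        rng = np.random.default_rng(3)
        base = rng.normal(18, 3, size=(40, 1))
        m = np.hstack([base, base + rng.normal(0, 0.3, (40, 1)),
                       base + 2.0 + rng.normal(0, 0.3, (40, 1))])
        out = bonferroni_pairwise(m, labels=["a", "b", "c"])
        assert out[("a", "c")][1] < 0.05
        assert out[("b", "c")][1] < 0.05
        assert out[("a", "b")][1] > 0.05
        raw_ac = paired_t(m[:, 0], m[:, 2]).p
        assert out[("a", "c")][0] == pytest.approx(raw_ac, rel=1e-12)


class TestPearson:
    def test_exact_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_worked_example(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_methods(self):
        x = np.array([1.0, 2.0, 3.0])
        assert bland_altman(x, x) == (0.0, 0.0, 0.0)

    def test_alternating_differences(self):
        """d = (1,-1,1,-1): sd = sqrt(4/3), LOA = -/+ 2.2632."""
        md, lo, hi = bland_altman([1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0])
        assert md == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * np.sqrt(4.0 / 3.0), abs=1e-4)
        assert lo == pytest.approx(-hi)

    def test_loa_cover_95_percent_of_differences(self):
        """For normal differences the LOA contain ~95% of points."""
        rng = np.random.default_rng(5)
        x = rng.normal(18, 3, 5000)
        y = x + rng.normal(0.8, 1.2, 5000)
        md, lo, hi = bland_altman(x, y)
        d = x - y
        frac = np.mean((d >= lo) & (d <= hi))
        assert abs(frac - 0.95) < 0.01

    def test_simulation_recovers_method_bias(self):
        """Generated study with software-vs-Hertel bias 0.78 mm recovers
        the Bland-Altman mean difference within 3 sigma / sqrt(n)."""
        spec = StudySpec(n_subjects=1000, eyes_per_subject=2, rater_sd=0.0,
                         strabismus_fraction=0.0, seed=17)
        table = MeasurementTable(generate_study(spec))
        wide = table.by_method()
        md, lo, hi = bland_altman(wide["software3d"], wide["hertel"])
        n = len(wide)
        sigma_d = np.hypot(spec.method_noise_sd["software3d"],
                           spec.method_noise_sd["hertel"])
        assert abs(md - 0.78) < 3 * sigma_d / np.sqrt(n) + 0.25 / np.sqrt(n)


class TestCronbachAlpha:
    def test_identical_repeats_give_one(self):
        col = np.random.default_rng(0).normal(18, 3, 12)
        m = np.tile(col[:, None], (1, 3))
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(8)
        m = rng.normal(0, 1, size=(5000, 3))
        assert abs(cronbach_alpha(m)) < 0.05

    def test_worked_table_against_direct_formula(self):
        m = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 5.0], [3.0, 5.0, 6.0], [5.0, 8.0, 9.0]])
        k = 3
        expected = k / (k - 1) * (1 - m.var(axis=0, ddof=1).sum() / m.sum(axis=1).var(ddof=1))
        assert cronbach_alpha(m) == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin(self, random_matrix):
        expected = pg.cronbach_alpha(data=pd.DataFrame(random_matrix))[0]
        assert cronbach_alpha(random_matrix) == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=30, derandomize=True)
    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.1, 20, allow_nan=False),
    )
    def test_location_scale_invariance(self, shift, scale):
        rng = np.random.default_rng(9)
        m = rng.normal(18, 3, size=(10, 3)) + rng.normal(0, 1, size=(10, 3))
        a0 = cronbach_alpha(m)
        assert cronbach_alpha(m * scale + shift) == pytest.approx(a0, abs=1e-8)

    def test_no_between_subject_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cronbach_alpha(np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]]))


class TestICC:
    def test_identical_raters_give_one(self):
        col = np.random.default_rng(0).normal(18, 3, 12)
        m = np.tile(col[:, None], (1, 3))
        assert icc(m, "icc2_1") == pytest.approx(1.0)
        assert icc(m, "icc3_1") == pytest.approx(1.0)

    def test_fixed_rater_offsets_consistency_vs_agreement(self):
        """Pure rater offsets: consistency ICC(3,1) stays 1 while absolute
        agreement ICC(2,1) drops below 1."""
        col = np.random.default_rng(1).normal(18, 3, 20)
        m = np.column_stack([col, col + 1.0, col - 2.0])
        assert icc(m, "icc3_1") == pytest.approx(1.0)
        assert icc(m, "icc2_1") < 1.0

    def test_matches_pingouin_forms(self, random_matrix):
        df = (
            pd.DataFrame(random_matrix, columns=list("ABC"))
            .reset_index()
            .melt(id_vars="index")
        )
        ref = pg.intraclass_corr(data=df, targets="index", raters="variable", ratings="value")
        assert icc(random_matrix, "icc2_1") == pytest.approx(
            float(ref[ref["Type"] == "ICC(A,1)"]["ICC"].iloc[0]), rel=1e-9
        )
        assert icc(random_matrix, "icc3_1") == pytest.approx(
            float(ref[ref["Type"] == "ICC(C,1)"]["ICC"].iloc[0]), rel=1e-9
        )

    def test_variance_ratio_recovery(self):
        """Subject sd 3, rater noise sd 1.5 -> ICC(2,1) ~ 9/11.25 = 0.8
        within +/- 0.05 at n = 500."""
        rng = np.random.default_rng(12)
        subjects = rng.normal(18, 3, size=(500, 1))
        m = subjects + rng.normal(0, 1.5, size=(500, 3))
        assert icc(m, "icc2_1") == pytest.approx(0.8, abs=0.05)

    def test_reliability_tends_to_one_as_noise_vanishes(self):
        """Both alpha and ICC approach 1 as repeat/rater noise shrinks in
        the study generator."""
        spec = StudySpec(
            n_subjects=100,
            method_noise_sd={"hertel": 0.01, "ct2d": 0.01, "software3d": 0.01},
            rater_sd=0.01,
            strabismus_extra_sd=0.0,
            seed=4,
        )
        table = MeasurementTable(generate_study(spec))
        assert cronbach_alpha(table.by_repeat("ct2d")) > 0.99
        assert icc(table.by_rater("ct2d"), "icc2_1") > 0.99


class TestMethodSummary:
    def _table_from_printed(self, means_sds):
        """Two readings per method reproducing a printed mean +/- SD
        exactly (values mean -/+ sd/sqrt(2))."""
        rows = []
        for method, (mean, sd) in means_sds.items():
            a = sd / np.sqrt(2.0)
            for unit, value in (("S0", mean - a), ("S1", mean + a)):
                rows.append((unit, "right", method, 1, "R1", value, "all"))
        return MeasurementTable(
            pd.DataFrame(rows, columns=["subject_id", "eye", "method", "repeat",
                                        "rater", "value_mm", "group"])
        )

    def test_pairwise_difference_exact_construction(self):
        table = self._table_from_printed({"hertel": (17.0, 1.0), "software3d": (17.78, 1.0)})
        out = method_summary(table)
        assert out["pairwise_mean_diff"][("hertel", "software3d")] == pytest.approx(-0.78)

    def test_printed_mean_and_sd_recovered(self):
        table = self._table_from_printed({"hertel": (17.78, 3.20), "ct2d": (19.21, 3.13)})
        out = method_summary(table)
        assert out["per_method"]["hertel"] == {"mean": 17.78, "sd": 3.2, "n": 2}
        assert out["pairwise_mean_diff"][("ct2d", "hertel")] == pytest.approx(1.43)

    def test_study_generator_means_recovered(self):
        spec = StudySpec(n_subjects=800, eyes_per_subject=1, rater_sd=0.0,
                         strabismus_fraction=0.0, seed=6)
        table = MeasurementTable(generate_study(spec))
        out = method_summary(table)
        for method in ("ct2d", "software3d"):
            expected = spec.truth_mean + spec.method_bias[method]
            sigma = np.hypot(spec.truth_sd, spec.method_noise_sd[method])
            tol = 3 * sigma / np.sqrt(800) + 0.005  # rounding to 2 decimals
            assert abs(out["per_method"][method]["mean"] - expected) < tol

    def test_single_subject_sd_not_available(self):
        df = pd.DataFrame(
            [("S0", "right", "hertel", 1, "R1", 17.0, "all"),
             ("S0", "left", "hertel", 1, "R1", 18.0, "all")],
            columns=["subject_id", "eye", "method", "repeat", "rater", "value_mm", "group"],
        )
        # two eyes of one subject are two units; restrict to one unit
        table = MeasurementTable(df)
        wide = table.by_method()
        assert wide.shape == (2, 1)

    def test_empty_group_rejected(self):
        table = self._table_from_printed({"hertel": (17.0, 1.0)})
        with pytest.raises(ValueError, match="group"):
            method_summary(table, group="missing")
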