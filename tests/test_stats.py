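"""Statistical layer against independent references (pingouin, scipy)."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from scfc.metrics import RichClubCurve
from scfc.stats import (
    ancova,
    chi_square_sex,
    curve_groups_test,
    partial_pearson,
)


def simulated_cohort_frame(n=60, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    groups = np.repeat(["NC", "MCI", "AD"], n // 3)
    shift = {"NC": 0.0, "MCI": effect, "AD": 2 * effect}
    df = pd.DataFrame(
        {
            "group": groups,
            "age": rng.normal(75, 8, n),
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
            "education": rng.normal(16, 3, n),
        }
    )
    df["y"] = (
        rng.normal(size=n)
        + 0.03 * df["age"]
        + np.array([shift[g] for g in groups])
    )
    return df


class TestAncova:
    def test_matches_pingouin_f_statistic(self):
        df = simulated_cohort_frame(seed=1, effect=0.8)
        df["sex_num"] = (df["sex"] == "F").astype(float)
        res = ancova(
            df["y"], df["group"], df[["age", "sex", "education"]], outcome_name="y"
        )
        ref = pg.ancova(data=df, dv="y", between="group",
                        covar=["age", "sex_num", "education"])
        ref_row = ref.loc[ref["Source"] == "group"].iloc[0]
        assert res.F == pytest.approx(float(ref_row["F"]), rel=1e-9)
        assert res.p == pytest.approx(float(ref_row["p_unc"]), rel=1e-9)

    def test_no_covariates_equals_one_way_anova(self):
        df = simulated_cohort_frame(seed=2, effect=0.5)
        res = ancova(df["y"], df["group"], None)
        groups = [df.loc[df["group"] == g, "y"] for g in sorted(df["group"].unique())]
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res.F == pytest.approx(f_ref)
        assert res.p == pytest.approx(p_ref)

    def test_orthogonal_covariates_leave_group_ss_unchanged(self):
        """Residualized covariates: the group sum of squares equals ANOVA's."""
        df = simulated_cohort_frame(seed=3, effect=0.5)
        g_dummies = pd.get_dummies(df["group"]).to_numpy(float)
        z = np.column_stack([g_dummies, df["y"].to_numpy()])
        raw = np.column_stack([df["age"], df["education"]])
        resid = raw - z @ np.linalg.lstsq(z, raw, rcond=None)[0]
        cov = pd.DataFrame(resid, columns=["age_o", "edu_o"])
        res = ancova(df["y"], df["group"], cov)
        plain = ancova(df["y"], df["group"], None)
        # the group and residual sums of squares are identical, so F scales
        # exactly with the residual degrees of freedom lost to the covariates
        assert res.df[1] == plain.df[1] - 2
        assert res.F / res.df[1] == pytest.approx(plain.F / plain.df[1], rel=1e-9)

    def test_adjusted_means_ordering_matches_planted_shift(self):
        df = simulated_cohort_frame(seed=4, effect=1.5)
        res = ancova(df["y"], df["group"], df[["age", "sex", "education"]])
        means = res.adjusted_group_means
        assert means["NC"] < means["MCI"] < means["AD"]

    def test_pairwise_bonferroni_and_consistency(self):
        df = simulated_cohort_frame(seed=5, effect=1.0)
        res = ancova(df["y"], df["group"], df[["age", "sex", "education"]])
        assert len(res.pairwise) == 3
        for pw in res.pairwise:
            assert pw["p_adjusted"] == pytest.approx(min(1.0, 3 * pw["p_raw"]))
            assert pw["p_adjusted"] >= pw["p_raw"]

    def test_zero_residual_variance_errors(self):
        groups = ["NC"] * 4 + ["AD"] * 4
        y = [1.0] * 4 + [2.0] * 4
        with pytest.raises(ValueError, match="residual"):
            ancova(y, groups, None)

    def test_collinear_design_errors(self):
        df = simulated_cohort_frame(seed=6)
        cov = df[["age"]].copy()
        cov["age2"] = cov["age"] * 2
        with pytest.raises(ValueError, match="rank-deficient"):
            ancova(df["y"], df["group"], cov)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            ancova([1.0, 2.0, 3.0], ["NC", "NC", "AD"], None)


class TestPartialPearson:
    def test_matches_pingouin(self):
        df = simulated_cohort_frame(seed=7)
        df["x"] = df["y"] * 0.5 + np.random.default_rng(99).normal(size=len(df))
        res = partial_pearson(df["x"], df["y"], df[["age", "education"]])
        ref = pg.partial_corr(data=df, x="x", y="y", covar=["age", "education"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_no_covariates_equals_plain_pearson(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = partial_pearson(x, y, None)
        ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        cov = pd.DataFrame({"c": rng.normal(size=30)})
        assert partial_pearson(x, x, cov).r == pytest.approx(1.0)

    def test_degenerate_after_residualization_errors(self):
        c = np.linspace(0, 1, 20)
        cov = pd.DataFrame({"c": c})
        with pytest.raises(ValueError, match="constant after residualization"):
            partial_pearson(2 * c + 1, 3 * c - 2, cov)


class TestChiSquare:
    def test_study_sex_table_statistic(self):
        # male/female 19/19, 20/20, 11/8 across the three groups
        groups = ["NC"] * 38 + ["MCI"] * 40 + ["AD"] * 19
        sexes = ["M"] * 19 + ["F"] * 19 + ["M"] * 20 + ["F"] * 20 + ["M"] * 11 + ["F"] * 8
        stat, p = chi_square_sex(groups, sexes)
        assert stat == pytest.approx(0.381, abs=0.005)

    def test_identical_ratios_give_zero(self):
        groups = ["NC"] * 4 + ["AD"] * 4
        sexes = ["M", "M", "F", "F"] * 2
        stat, _ = chi_square_sex(groups, sexes)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_textbook_formula(self):
        # counts: NC(10 M, 5 F), AD(4 M, 11 F) -> chi2 = n(ad-bc)^2/(r1 r2 c1 c2)
        groups = ["NC"] * 15 + ["AD"] * 15
        sexes = ["M"] * 10 + ["F"] * 5 + ["M"] * 4 + ["F"] * 11
        stat, _ = chi_square_sex(groups, sexes)
        expected = 30 * (10 * 11 - 5 * 4) ** 2 / (15 * 15 * 14 * 16)
        assert stat == pytest.approx(expected)

    def test_empty_column_errors(self):
        with pytest.raises(ValueError, match="empty"):
            chi_square_sex(["NC", "AD"], ["M", "M"])


class TestCurveGroupsTest:
    def _curves(self, shift_at=None, n_per_group=8, seed=0):
        rng = np.random.default_rng(seed)
        curves, groups, cov_rows = {}, {}, []
        k = np.arange(1, 11)
        for g in ("NC", "MCI", "AD"):
            for i in range(n_per_group):
                phi = 0.5 + 0.02 * k + rng.normal(0, 0.02, size=len(k))
                if shift_at is not None and g != "NC":
                    phi[shift_at - 1] += 0.25
                sid = f"{g}{i}"
                curves[sid] = RichClubCurve(k_values=k, phi=phi)
                groups[sid] = g
                cov_rows.append({"age": rng.normal(75, 5),
                                 "sex": "F" if rng.random() < 0.5 else "M",
                                 "education": rng.normal(16, 2)})
        return curves, groups, pd.DataFrame(cov_rows)

    def test_identical_curves_give_near_zero_f(self):
        k = np.arange(1, 6)
        curves = {}
        groups = {}
        for g in ("NC", "MCI", "AD"):
            for i in range(5):
                sid = f"{g}{i}"
                # identical shape plus per-subject noise shared across k
                curves[sid] = RichClubCurve(k_values=k, phi=0.3 + 0.01 * k + i * 1e-3)
                groups[sid] = g
        out = curve_groups_test(curves, groups, None)
        assert (out["F"] < 1e-10).all()
        assert (out["p"] > 0.999).all()

    def test_planted_shift_detected_at_the_right_k(self):
        curves, groups, cov = self._curves(shift_at=4, seed=1)
        out = curve_groups_test(curves, groups, cov).set_index("k")
        assert out.loc[4, "p_adjusted"] < 0.05
        others = out.drop(index=4)
        assert (others["p_adjusted"] > 0.2).all()

    def test_undefined_entries_drop_subjects_and_record_n(self):
        curves, groups, cov = self._curves(seed=2)
        sid = next(iter(curves))
        curves[sid].phi[2] = np.nan  # undefined at k=3 for one subject
        out = curve_groups_test(curves, groups, cov).set_index("k")
        assert out.loc[3, "n"] == len(curves) - 1
        assert out.loc[4, "n"] == len(curves)

    def test_bonferroni_factor_is_number_of_tested_k(self):
        curves, groups, cov = self._curves(seed=3)
        out = curve_groups_test(curves, groups, cov)
        assert (out["m_tests"] == len(out)).all()
        np.testing.assert_allclose(
            out["p_adjusted"], np.minimum(1.0, out["p"] * len(out))
        )
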