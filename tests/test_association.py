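"""Regression fits, group comparisons, power/sample-size arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methmorph import (
    PowerSpec,
    compare_groups,
    default_cohort_params,
    fit_linear,
    required_sample_size,
    simulate_cohort,
    stage_association_report,
)
from methmorph.synthetic import MM_GROUPS, TABLE_COEFFICIENTS


def _ols_oracle(x, y):
    """Closed-form normal equations plus slope t-test (independent route)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    s2 = (resid**2).sum() / (n - 2)
    se = math.sqrt(s2 / sxx)
    t = slope / se if se > 0 else math.inf
    p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, intercept, p


class TestFitLinear:
    def test_noiseless_points_recover_reported_equation(self):
        # generated from the intraosseous miR-23-on-uPA relation
        x = np.arange(10, dtype=float)
        y = -0.3209 * x + 1.332
        fit = fit_linear(x, y)
        assert fit.slope == pytest.approx(-0.3209, rel=1e-4)
        assert fit.intercept == pytest.approx(1.332, rel=1e-4)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.equation == "Y = -0.3209*X + 1.332"

    def test_identity_line(self):
        fit = fit_linear(np.arange(5.0), np.arange(5.0))
        assert fit.slope == pytest.approx(1.0) and fit.intercept == pytest.approx(0.0)
        assert fit.p_slope < 0.001

    def test_agrees_with_closed_form_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + rng.normal() * x
            fit = fit_linear(x, y)
            slope, intercept, p = _ols_oracle(x, y)
            assert fit.slope == pytest.approx(slope, rel=1e-10)
            assert fit.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-12)
            assert fit.p_slope == pytest.approx(p, rel=1e-8)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_linear([1.0, 2.0], [1.0, 2.0])

    def test_type_one_error_of_slope_test(self):
        # under the null (independent x, y), P(p < 0.05) should be ~0.05
        rng = np.random.default_rng(123)
        n, reps = 20, 2000
        hits = 0
        for _ in range(reps):
            if fit_linear(rng.normal(size=n), rng.normal(size=n)).p_slope < 0.05:
                hits += 1
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_negative_intercept_rendering(self):
        fit = fit_linear(np.arange(5.0), 2.0 * np.arange(5.0) - 1.5)
        assert fit.equation == "Y = 2*X - 1.5"


class TestStageAssociationReport:
    def test_noiseless_cohort_reproduces_generating_coefficients(self):
        cohort = simulate_cohort(default_cohort_params(seed=4, noise_scale=0.0))
        report = stage_association_report(cohort)
        for g in MM_GROUPS:
            sub = report[report["group"] == g].set_index("association")
            am, bm, _ = TABLE_COEFFICIENTS[g]["mir23_on_meth"]
            au, bu, _ = TABLE_COEFFICIENTS[g]["upa_on_meth"]
            row = sub.loc["miR-23 with methylation"]
            assert row["slope"] == pytest.approx(am, rel=1e-4)
            assert row["intercept"] == pytest.approx(bm, rel=1e-4)
            row = sub.loc["uPA with methylation"]
            assert row["slope"] == pytest.approx(au, rel=1e-4)
            assert row["intercept"] == pytest.approx(bu, rel=1e-4)

    def test_default_cohort_slope_signs(self):
        report = stage_association_report(simulate_cohort(default_cohort_params(seed=5)))
        assert report["sign_ok"].all()
        assert len(report) == 12  # 4 stages x 3 associations

    def test_permuted_methylation_breaks_associations(self):
        rng = np.random.default_rng(9)
        null_fraction = []
        for rep in range(100):
            cohort = simulate_cohort(default_cohort_params(seed=1000 + rep))
            cohort = cohort.assign(meth_rate=rng.permutation(cohort["meth_rate"].to_numpy()))
            report = stage_association_report(cohort)
            meth_rows = report[report["association"] != "uPA with miR-23"]
            null_fraction.append((meth_rows["p_slope"] > 0.05).all())
        assert np.mean(null_fraction) >= 0.45  # 8 tests at alpha 0.05: ~0.66 expected

    def test_missing_column_rejected(self):
        cohort = simulate_cohort(default_cohort_params(seed=0)).drop(columns=["upa"])
        with pytest.raises(ValueError):
            stage_association_report(cohort)

    def test_slope_recovery_within_two_standard_errors(self):
        from methmorph.association import fit_linear as fl

        hits = total = 0
        for rep in range(200):
            cohort = simulate_cohort(default_cohort_params(seed=2000 + rep))
            for g in MM_GROUPS:
                sub = cohort[cohort["group"] == g]
                fit = fl(sub["meth_rate"], sub["mir23"])
                true = TABLE_COEFFICIENTS[g]["mir23_on_meth"][0]
                hits += abs(fit.slope - true) < 2 * fit.stderr
                total += 1
        assert hits / total >= 0.93


class TestCompareGroups:
    def test_identical_groups_are_null(self):
        comp = compare_groups({"a": [1.0] * 5, "b": [1.0] * 5, "c": [1.0] * 5})
        assert comp.anova_f == 0.0 and comp.anova_p == 1.0
        assert not comp.pairwise["significant"].any()

    def test_separated_groups_flagged_with_power(self):
        # mirrors "lowest group differs, two middle groups equal" design
        rng = np.random.default_rng(77)
        flag_low, flag_mid = [], []
        for _ in range(200):
            groups = {
                "intra": rng.normal(1, 0.5, 10),
                "blood": rng.normal(3, 0.5, 10),
                "bone": rng.normal(3, 0.5, 10),
                "extra": rng.normal(6, 0.5, 10),
            }
            comp = compare_groups(groups)
            pw = comp.pairwise.set_index(["group_a", "group_b"])
            flag_low.append(
                pw.loc[("intra", "blood"), "significant"]
                and pw.loc[("intra", "bone"), "significant"]
                and pw.loc[("intra", "extra"), "significant"]
            )
            flag_mid.append(bool(pw.loc[("blood", "bone"), "significant"]))
        assert np.mean(flag_low) > 0.9
        assert np.mean(flag_mid) < 0.2

    def test_bonferroni_multiplier_for_four_groups(self):
        rng = np.random.default_rng(5)
        comp = compare_groups({g: rng.normal(size=8) for g in "abcd"})
        assert comp.n_comparisons == 6
        pw = comp.pairwise
        assert np.allclose(pw["p_adj"], np.minimum(1.0, 6 * pw["p_raw"]))
        # adjusted flags are a subset of raw flags
        assert not ((pw["p_adj"] < 0.05) & ~(pw["p_raw"] < 0.05)).any()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})

    def test_mean_ordering_summary(self):
        comp = compare_groups({"lo": [1.0, 1.1], "hi": [9.0, 9.1], "mid": [5.0, 5.1]})
        assert comp.mean_order == ("lo", "mid", "hi")


class TestRequiredSampleSize:
    def test_unit_effect_size(self):
        # 2 * (1.95996 + 0.84162)^2 = 15.70 -> 16
        assert required_sample_size(PowerSpec(effect_size=1.0)) == 16

    def test_double_effect_size(self):
        assert required_sample_size(PowerSpec(effect_size=2.0)) == 4

    def test_n_grows_as_effect_shrinks(self):
        sizes = [required_sample_size(PowerSpec(effect_size=d)) for d in (2.0, 1.0, 0.5, 0.2, 0.1)]
        assert sizes == sorted(sizes)
        assert sizes[-1] > 1000

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            PowerSpec(effect_size=0.0)
        with pytest.raises(ValueError):
            PowerSpec(alpha=1.5)
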