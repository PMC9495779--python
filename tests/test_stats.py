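import itertools

import numpy as np
import pandas as pd
import pytest

from pdfftexture.io_maps import FEATURE_NAMES
from pdfftexture.stats import (
    SubjectRecord,
    ks_normality,
    logistic_wald,
    mann_whitney,
    partial_correlation,
    run_cohort_analysis,
    sex_difference_logistic,
)


def exact_mw_p(a, b):
    """Exhaustive permutation oracle for the two-sided Mann-Whitney test:
    enumerate every labeling of the pooled sample and count U statistics at
    least as extreme (in either tail) as the observed one."""
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_stat(x, y):
        return sum(1 for xi in x for yi in y if xi > yi) \
            + 0.5 * sum(1 for xi in x for yi in y if xi == yi)

    u_obs = u_stat(a, b)
    mean_u = n_a * len(b) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        total += 1
        if abs(u_stat(x, y) - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_exact_small_sample_matches_enumeration(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        res = mann_whitney(a, b)
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(exact_mw_p(a, b))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exact_matches_enumeration_random(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 4), rng.normal(0.5, 1, 5)
        assert mann_whitney(a, b).p_value == pytest.approx(exact_mw_p(a, b))

    def test_identical_groups_p_one(self):
        a = np.arange(1.0, 7.0)
        assert mann_whitney(a, a.copy()).p_value == pytest.approx(1.0)

    def test_large_shift_detected(self, rng):
        a = rng.normal(0, 1, 20)
        assert mann_whitney(a, a + 10.0).p_value < 1e-3

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney(np.array([]), np.array([1.0]))


class TestKS:
    def test_normal_sample_passes(self, rng):
        assert ks_normality(rng.normal(5, 2, 5000)).p_value > 0.05

    def test_exponential_sample_fails(self, rng):
        assert ks_normality(rng.exponential(1.0, 5000)).p_value < 0.05

    def test_constant_flagged(self):
        res = ks_normality(np.full(10, 3.0))
        assert "zero_variance" in res.flags


class TestPartialCorrelation:
    def test_orthogonal_covariates_reduce_to_pearson(self, rng):
        n = 200
        x, y = rng.normal(size=n), rng.normal(size=n)
        z = np.zeros((n, 1)) + rng.normal(size=(n, 1)) * 0.0  # constant covariate
        # use a covariate exactly orthogonal to x and y residual spaces:
        z = np.ones((n, 1)) * 2.0
        res = partial_correlation(x, y, z + rng.normal(size=(n, 1)) * 0)
        plain = np.corrcoef(x, y)[0, 1]
        assert res.statistic == pytest.approx(plain, abs=1e-10)

    def test_x_equals_y_gives_one(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=(50, 2))
        assert partial_correlation(x, x, z).statistic == pytest.approx(1.0)

    def test_single_covariate_recursive_formula(self, rng):
        n = 120
        age = rng.normal(45, 15, n)
        x = 0.5 * age + rng.normal(size=n) * 8
        y = -0.3 * age + rng.normal(size=n) * 8
        res = partial_correlation(x, y, age.reshape(-1, 1))
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, age)[0, 1]
        r_yz = np.corrcoef(y, age)[0, 1]
        closed = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert res.statistic == pytest.approx(closed, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 60
        df = pd.DataFrame({
            "x": rng.normal(size=n), "y": rng.normal(size=n),
            "age": rng.normal(45, 10, n), "bmi": rng.normal(25, 4, n),
        })
        df["x"] += 0.3 * df["age"]
        df["y"] += 0.2 * df["age"]
        res = partial_correlation(df["x"].to_numpy(), df["y"].to_numpy(),
                                  df[["age", "bmi"]].to_numpy())
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["age", "bmi"])
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_constant_after_residualization_flagged(self, rng):
        z = rng.normal(size=(30, 1))
        x = 3.0 * z[:, 0] + 1.0  # exactly linear in the covariate
        y = rng.normal(size=30)
        res = partial_correlation(x, y, z)
        assert "constant_residual" in res.flags


class TestLogistic:
    def _cohort(self, rng, n_m=13, n_f=31, beta=0.0):
        male = np.r_[np.ones(n_m), np.zeros(n_f)]
        age = np.r_[rng.normal(55, 20, n_m), rng.normal(39, 15, n_f)]
        bmi = rng.normal(25, 4, n_m + n_f)
        feature = rng.normal(size=n_m + n_f) + beta * male
        return feature, male, age, bmi

    def test_wald_p_invariant_to_feature_rescaling(self, rng):
        f, male, age, bmi = self._cohort(rng, beta=1.0)
        a = logistic_wald(f, male, age, bmi)
        b = logistic_wald(f * 1000.0 - 77.0, male, age, bmi)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-6)

    def test_effect_direction_sign(self, rng):
        f, male, age, bmi = self._cohort(rng, beta=3.0)
        res = logistic_wald(f, male, age, bmi)
        assert res.direction == 1
        assert res.p_value < 0.05

    def test_separation_triggers_penalized_path(self, rng):
        male = np.r_[np.ones(10), np.zeros(10)]
        feature = np.r_[rng.uniform(10, 11, 10), rng.uniform(0, 1, 10)]
        age = rng.normal(45, 10, 20)
        res = logistic_wald(feature, male, age, None)
        assert "separation_penalized_fit" in res.flags
        assert 0 <= res.p_value <= 1

    def test_single_sex_raises(self, rng):
        f = rng.normal(size=10)
        with pytest.raises(ValueError, match="both sexes"):
            logistic_wald(f, np.ones(10), f, f)


def make_feature_table(rng, n_m=13, n_f=31, compartments=("ES", "PS", "LS")):
    rows = []
    for i in range(n_m + n_f):
        sex = "male" if i < n_m else "female"
        age = rng.uniform(20, 80)
        bmi = rng.uniform(19, 33)
        for comp in compartments:
            row = {"subject_id": f"S{i:03d}", "compartment": comp,
                   "sex": sex, "age": age, "bmi": bmi}
            row.update({k: float(rng.normal(10, 3)) for k in FEATURE_NAMES})
            rows.append(row)
    return pd.DataFrame(rows)


class TestCohortAnalysis:
    def test_output_layout(self, rng):
        df = make_feature_table(rng)
        res = run_cohort_analysis(df)
        t1_features = res.table1[res.table1["compartment"] != ""]
        assert len(t1_features) == 36          # 12 features x 3 compartments
        assert len(res.table2) == 24           # 12 features x {LS-ES, LS-PS}
        assert set(res.table2["comparison"]) == {"LS_vs_ES", "LS_vs_PS"}
        assert ((res.table2["p_value"] >= 0) & (res.table2["p_value"] <= 1)).all()

    def test_single_sex_skips_logistic(self, rng):
        df = make_feature_table(rng, n_m=0, n_f=20)
        res = run_cohort_analysis(df)
        assert (res.table1["method"].str.contains("skipped")).any()
        assert "single-sex" in res.report

    def test_fdr_adds_adjusted_column(self, rng):
        df = make_feature_table(rng)
        res = run_cohort_analysis(df, fdr=True)
        assert "p_adjusted" in res.table1.columns
        ok = res.table1["p_value"].notna()
        assert (res.table1.loc[ok, "p_adjusted"] >= res.table1.loc[ok, "p_value"] - 1e-12).all()

    def test_planted_cross_compartment_correlation_detected(self, rng):
        df = make_feature_table(rng)
        # plant a strong LS-ES association in variance_global
        wide = df.pivot(index="subject_id", columns="compartment")
        shared = rng.normal(size=wide.shape[0])
        for comp in ("ES", "LS"):
            sel = df["compartment"] == comp
            df.loc[sel, "variance_global"] = (
                10 + 3 * shared[np.searchsorted(wide.index.to_numpy(),
                                                df.loc[sel, "subject_id"].to_numpy())]
                + rng.normal(size=sel.sum())
            )
        res = run_cohort_analysis(df)
        row = res.table2[(res.table2["feature"] == "variance_global")
                         & (res.table2["comparison"] == "LS_vs_ES")].iloc[0]
        assert row["partial_r"] > 0.5
        assert row["significant"]


class TestSubjectRecord:
    def test_invalid_sex_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            SubjectRecord("S1", "other", 30.0, 22.0, {})

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SubjectRecord("S1", "male", 0.0, 22.0, {})
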