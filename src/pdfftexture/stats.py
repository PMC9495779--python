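"""Cohort statistics for per-compartment texture features.

Implements the study-style analysis: a Kolmogorov-Smirnov normality screen,
Mann-Whitney comparisons for demographics, per-feature logistic regression of
sex on each feature adjusted for age and BMI (Wald p-values), and partial
correlations between lumbar-spine and muscle features adjusted for age and
BMI. All tests are two-sided; no multiple-testing correction is applied by
default (each test at alpha = 0.05), with Benjamini-Hochberg available as an
option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .aggregate import FeatureVector
from .io_maps import FEATURE_NAMES

COMPARTMENTS = ("ES", "PS", "LS")


@dataclass
class SubjectRecord:
    """One subject: demographics plus a FeatureVector per compartment."""

    subject_id: str
    sex: str  # "male" | "female"
    age: float
    bmi: float
    features: dict[str, FeatureVector]

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (self.age > 0 and self.bmi > 0):
            raise ValueError("age and BMI must be positive")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    direction: int = 0  # sign of the effect (per the documented coding)
    n: int = 0
    method: str = ""
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def ks_normality(values: np.ndarray) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against a normal with the sample's
    own mean and SD (the routine normality screen of standard stats software).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 5:
        raise ValueError("need at least 5 values for the normality screen")
    sd = values.std(ddof=1)
    if sd <= 0:
        return TestResult(np.nan, np.nan, n=values.size, method="ks_normal",
                          flags={"zero_variance"})
    stat, p = sps.kstest(values, "norm", args=(values.mean(), sd))
    return TestResult(float(stat), float(p), n=values.size, method="ks_normal")


def mann_whitney(group_a: np.ndarray, group_b: np.ndarray) -> TestResult:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, otherwise
    the tie-corrected normal approximation."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size <= 8 and b.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = int(np.sign(np.median(a) - np.median(b)))
    return TestResult(float(res.statistic), float(res.pvalue), direction=direction,
                      n=a.size + b.size, method=f"mann_whitney_{method}")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd <= 0:
        raise ValueError("constant predictor")
    return (x - x.mean()) / sd


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Jeffreys-prior penalized logistic fit (Firth's correction).

    Used when plain maximum likelihood diverges under (quasi-)separation;
    returns (beta, covariance) with covariance the inverse penalized
    information, from which Wald statistics are formed.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        cov = np.linalg.pinv(info)
        # diagonal of the hat matrix W^1/2 X (X'WX)^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", X * w[:, None], cov, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = cov @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    cov = np.linalg.pinv((X.T * w) @ X)
    return beta, cov


def logistic_wald(
    feature: np.ndarray,
    male: np.ndarray,
    age: np.ndarray,
    bmi: np.ndarray | None = None,
    adjust: bool = True,
) -> TestResult:
    """Wald test of the feature coefficient in logit P(male) ~ feature [+ age + BMI].

    The feature (and covariates) are z-scored internally for numerical
    stability; the Wald p-value is invariant to affine rescaling. Separation
    or ML non-convergence falls back to a Firth-penalized fit, flagged.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(male, dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("male indicator must be 0/1")
    if y.min() == y.max():
        raise ValueError("both sexes must be present")
    cols = [_zscore(np.asarray(feature, dtype=np.float64))]
    if adjust:
        cols.append(_zscore(np.asarray(age, dtype=np.float64)))
        if bmi is not None:
            cols.append(_zscore(np.asarray(bmi, dtype=np.float64)))
    X = sm.add_constant(np.column_stack(cols))
    flags: set[str] = set()
    beta = se = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if fit.mle_retvals.get("converged", False) and np.max(np.abs(fit.params)) < 25:
                beta = fit.params
                se = fit.bse
        except (PerfectSeparationError, np.linalg.LinAlgError):
            pass
    if beta is None or not np.all(np.isfinite(se)):
        flags.add("separation_penalized_fit")
        b, cov = _firth_logit(X, y)
        beta = b
        se = np.sqrt(np.diag(cov))
    z = beta[1] / se[1]
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(float(z), float(p), direction=int(np.sign(beta[1])),
                      n=y.size, method="logistic_wald" + ("" if adjust else "_unadjusted"),
                      flags=flags)


def sex_difference_logistic(df: pd.DataFrame, feature_name: str, compartment: str,
                            adjust: bool = True) -> TestResult:
    """Sex difference of one feature in one compartment, adjusted for age and
    BMI. ``df`` is the long feature table (one row per subject-compartment).
    Male is coded 1, so a positive direction means higher values in males."""
    sub = df[df["compartment"] == compartment]
    male = (sub["sex"] == "male").to_numpy(dtype=float)
    return logistic_wald(sub[feature_name].to_numpy(), male,
                         sub["age"].to_numpy(), sub["bmi"].to_numpy(), adjust=adjust)


def residualize(x: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Least-squares residual of x on [1, covariates]."""
    x = np.asarray(x, dtype=np.float64)
    Z = np.column_stack([np.ones(x.size), np.asarray(covariates, dtype=np.float64)])
    coef, *_ = np.linalg.lstsq(Z, x, rcond=None)
    return x - Z @ coef


def partial_correlation(x: np.ndarray, y: np.ndarray, covariates: np.ndarray) -> TestResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [1, covariates] by least squares; the
    Pearson correlation of the residuals is tested with
    t = r sqrt((n - 2 - k) / (1 - r^2)) on n - 2 - k degrees of freedom,
    k the number of covariates.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    Z = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
    if Z.shape[0] == x.size and Z.ndim == 2:
        k = Z.shape[1] if Z.ndim == 2 else 1
    else:
        Z = Z.T
        k = Z.shape[1]
    n = x.size
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    rx = residualize(x, Z)
    ry = residualize(y, Z)
    sx, sy = rx.std(), ry.std()
    # residuals indistinguishable from zero at float precision count as constant
    if sx <= 1e-10 * max(x.std(), 1.0) or sy <= 1e-10 * max(y.std(), 1.0):
        return TestResult(np.nan, np.nan, n=n, method="partial_correlation",
                          flags={"constant_residual"})
    r = float(np.dot(rx, ry) / (n * sx * sy))
    r = max(-1.0, min(1.0, r))
    dof = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), dof))
    return TestResult(r, p, direction=int(np.sign(r)), n=n, method="partial_correlation")


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    mask = np.isfinite(pvals)
    out = np.full_like(np.asarray(pvals, dtype=float), np.nan)
    if mask.sum():
        out[mask] = multipletests(np.asarray(pvals)[mask], method="fdr_bh")[1]
    return out


@dataclass
class AnalysisResults:
    table1: pd.DataFrame
    table2: pd.DataFrame
    report: str
    normality: pd.DataFrame


def run_cohort_analysis(df: pd.DataFrame, alpha: float = 0.05, fdr: bool = False) -> AnalysisResults:
    """Full cohort analysis of a long feature table.

    Emits a demographics-and-features summary (group means +- SD by sex with
    a Mann-Whitney p for age/BMI and an adjusted logistic Wald p per feature
    per compartment) and a partial-correlation table (each feature, lumbar
    spine vs each muscle group, adjusted for age and BMI). Flagged results
    propagate without aborting the bundle; a single-sex cohort skips the
    logistic section with a diagnostic.
    """
    subjects = df.drop_duplicates("subject_id")
    sexes = set(subjects["sex"])
    both_sexes = {"male", "female"} <= sexes
    males = subjects[subjects["sex"] == "male"]
    females = subjects[subjects["sex"] == "female"]

    t1_rows = []
    notes: list[str] = []
    for var in ("age", "bmi"):
        row = {
            "variable": var, "compartment": "",
            "male_mean": males[var].mean(), "male_sd": males[var].std(ddof=1),
            "female_mean": females[var].mean(), "female_sd": females[var].std(ddof=1),
        }
        if both_sexes:
            res = mann_whitney(males[var].to_numpy(), females[var].to_numpy())
            row.update(p_value=res.p_value, method=res.method)
        else:
            row.update(p_value=np.nan, method="skipped_single_sex")
        t1_rows.append(row)

    norm_rows = []
    for comp in COMPARTMENTS:
        sub = df[df["compartment"] == comp]
        if sub.empty:
            continue
        for feat in FEATURE_NAMES:
            vals = sub[feat].to_numpy(dtype=float)
            if np.isnan(vals).any():
                continue
            try:
                ks = ks_normality(vals)
                norm_rows.append({"compartment": comp, "feature": feat,
                                  "ks_stat": ks.statistic, "p_value": ks.p_value})
            except ValueError:
                pass
            m = sub[sub["sex"] == "male"][feat]
            f = sub[sub["sex"] == "female"][feat]
            row = {
                "variable": feat, "compartment": comp,
                "male_mean": m.mean(), "male_sd": m.std(ddof=1),
                "female_mean": f.mean(), "female_sd": f.std(ddof=1),
            }
            if both_sexes:
                try:
                    res = sex_difference_logistic(df, feat, comp)
                    row.update(p_value=res.p_value, method=res.method,
                               direction=res.direction)
                    if res.flags:
                        notes.append(f"{comp}/{feat}: {','.join(sorted(res.flags))}")
                except (ValueError, np.linalg.LinAlgError) as exc:
                    row.update(p_value=np.nan, method="failed")
                    notes.append(f"{comp}/{feat}: logistic fit failed ({exc})")
            else:
                row.update(p_value=np.nan, method="skipped_single_sex")
            t1_rows.append(row)
    table1 = pd.DataFrame(t1_rows)
    if not both_sexes:
        notes.append("single-sex cohort: logistic regression section skipped")

    # partial correlations: lumbar spine vs each muscle compartment
    wide = df.pivot(index="subject_id", columns="compartment")
    cov = subjects.set_index("subject_id").loc[wide.index, ["age", "bmi"]].to_numpy()
    t2_rows = []
    for muscle in ("ES", "PS"):
        for feat in FEATURE_NAMES:
            try:
                x = wide[(feat, "LS")].to_numpy(dtype=float)
                y = wide[(feat, muscle)].to_numpy(dtype=float)
            except KeyError:
                continue
            if np.isnan(x).any() or np.isnan(y).any():
                continue
            res = partial_correlation(x, y, cov)
            t2_rows.append({"feature": feat, "comparison": f"LS_vs_{muscle}",
                            "partial_r": res.statistic, "p_value": res.p_value,
                            "n": res.n})
    table2 = pd.DataFrame(t2_rows)

    if fdr:
        table1["p_adjusted"] = bh_adjust(table1["p_value"].to_numpy())
        table2["p_adjusted"] = bh_adjust(table2["p_value"].to_numpy())
    pcol = "p_adjusted" if fdr else "p_value"
    table1["significant"] = table1[pcol] < alpha
    table2["significant"] = table2[pcol] < alpha

    normality = pd.DataFrame(norm_rows)
    lines = [
        "Cohort texture-feature analysis",
        f"subjects: {len(subjects)} ({len(males)} male, {len(females)} female)",
        f"alpha = {alpha} (two-sided){', BH-adjusted' if fdr else ''}",
        "",
        "Sex differences (logistic regression adjusted for age and BMI):",
    ]
    sig1 = table1[(table1["compartment"] != "") & table1["significant"].fillna(False)]
    for _, r in sig1.iterrows():
        lines.append(f"  {r['compartment']:>3} {r['variable']:<18} p = {r['p_value']:.4f}")
    if sig1.empty:
        lines.append("  none significant")
    lines += ["", "Partial correlations LS vs muscles (adjusted for age and BMI):"]
    sig2 = table2[table2["significant"].fillna(False)]
    for _, r in sig2.iterrows():
        lines.append(f"  {r['comparison']:<9} {r['feature']:<18} r = {r['partial_r']:+.2f}, p = {r['p_value']:.4f}")
    if sig2.empty:
        lines.append("  none significant")
    if norm_rows:
        frac_normal = float(np.mean(normality["p_value"] > alpha))
        lines += ["", f"KS normality screen: {frac_normal:.0%} of feature distributions consistent with normality"]
    if notes:
        lines += ["", "Diagnostics:"] + [f"  {n}" for n in notes]
    return AnalysisResults(table1=table1, table2=table2, report="\n".join(lines),
                           normality=normality)
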