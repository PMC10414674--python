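"""Measurement-properties statistics: validity, reproducibility,
interpretability.

Criterion validity of a device against a gold standard is summarized by the
Pearson correlation (with a Shapiro-Wilk normality pre-check), Lin's
concordance correlation coefficient (CCC), the mean absolute relative
measurement error, and Bland-Altman limits of agreement.  Test-retest
reproducibility uses the intraclass correlation ICC(2,1) (two-way random
effects, absolute agreement, single measurement, Shrout-Fleiss ANOVA
estimator with F-based confidence bounds) and, when covariates should be
held fixed, a covariate-adjusted linear mixed model fitted by REML.
Interpretability converts the error variance into the standard error of
measurement SEM = sqrt(VarError) and the minimal detectable change
MDC = 1.96 * sqrt(2) * SEM.  An ICC-based sample-size calculation
(Walter-Eliasziw-Donner approximation) and qualitative coefficient grading
round out the pipeline.

Paired and repeated-measures data travel as pandas DataFrames:

* paired table: columns ``device`` and ``gold`` (one row per measurement);
* repeated-measures table: columns ``subject``, ``session``, ``score`` and
  optionally per-subject covariates (``age``, ``bmi``, ``phone_brand``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateDesignError,
    EstimationFailureError,
    InfeasibleDesignError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedStatisticError,
)

__all__ = [
    "ValidityReport",
    "ReliabilityReport",
    "IccResult",
    "pearson_with_normality",
    "lins_ccc",
    "relative_measurement_error",
    "bland_altman",
    "icc_2_1",
    "icc_mixed_adjusted",
    "sem_mdc",
    "within_subject_cv",
    "icc_sample_size",
    "icc_power_simulation",
    "grade_coefficient",
    "validity_report",
    "reliability_report",
]


# ---------------------------------------------------------------------------
# report containers


@dataclass
class ValidityReport:
    pearson_r: float
    pearson_p: float
    shapiro_p: float
    ccc: float
    ccc_ci: tuple[float, float]
    mean_abs_rme: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    grade_r: str
    grade_ccc: str
    n: int

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "shapiro_p": self.shapiro_p,
            "ccc": self.ccc,
            "ccc_ci": list(self.ccc_ci),
            "mean_abs_rme_percent": self.mean_abs_rme,
            "bland_altman": {
                "mean_diff": self.mean_diff,
                "sd_diff": self.sd_diff,
                "loa_low": self.loa_low,
                "loa_high": self.loa_high,
            },
            "grade_r": self.grade_r,
            "grade_ccc": self.grade_ccc,
            "n": self.n,
        }


@dataclass
class ReliabilityReport:
    icc: float
    icc_ci: tuple[float, float]
    var_between: float
    var_error: float
    sem: float
    cv: float
    mdc: float
    mdc_percent: float
    grand_mean: float
    model: str  # "anova" or "mixed"
    n_subjects: int
    n_sessions: int

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "icc_ci": list(self.icc_ci),
            "var_between": self.var_between,
            "var_error": self.var_error,
            "sem": self.sem,
            "cv_percent": self.cv,
            "mdc": self.mdc,
            "mdc_percent": self.mdc_percent,
            "grand_mean": self.grand_mean,
            "model": self.model,
            "n_subjects": self.n_subjects,
            "n_sessions": self.n_sessions,
        }


@dataclass
class IccResult:
    icc: float
    ci: tuple[float, float]
    var_between: float
    var_error: float
    msr: float
    msc: float
    mse: float
    n: int
    k: int


# ---------------------------------------------------------------------------
# validity


def _paired_arrays(device, gold, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(device, dtype=float)
    y = np.asarray(gold, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("device and gold must be 1-D arrays of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < min_n:
        raise InsufficientDataError(f"need at least {min_n} complete pairs, got {x.size}")
    return x, y


def pearson_with_normality(device, gold) -> tuple[float, float, float]:
    """Pearson r with its p-value and a Shapiro-Wilk normality pre-check.

    The Shapiro-Wilk test runs on each margin; the smaller p is reported
    (a small value warns that the correlation's parametric p-value rests
    on a shaky normality assumption).
    """
    x, y = _paired_arrays(device, gold, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a zero-variance margin")
    r, p = stats.pearsonr(x, y)
    shapiro_p = min(stats.shapiro(x).pvalue, stats.shapiro(y).pvalue)
    return float(r), float(p), float(shapiro_p)


def lins_ccc(device, gold, ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with a z-transform CI.

    CCC = 2*s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2) with population
    (n-denominator) moments, so |CCC| <= |r| always, with equality only
    when the identity line fits in both location and scale.  The CI uses
    Lin's variance for atanh(CCC) (corrected form).
    """
    x, y = _paired_arrays(device, gold, 3)
    n = x.size
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    d2 = float((x.mean() - y.mean()) ** 2)
    if sx2 == 0 and sy2 == 0:
        raise UndefinedStatisticError("CCC undefined when both margins are constant")
    denom = sx2 + sy2 + d2
    ccc = 2.0 * sxy / denom
    if sx2 == 0 or sy2 == 0 or abs(ccc) >= 1.0 - 1e-15:
        return float(ccc), (float(ccc), float(ccc))
    r = sxy / math.sqrt(sx2 * sy2)
    u2 = d2 / math.sqrt(sx2 * sy2)
    z = math.atanh(ccc)
    c2 = ccc * ccc
    se2 = (
        (1 - r * r) * c2 / ((1 - c2) * r * r)
        + 4 * ccc ** 3 * (1 - ccc) * u2 / (r * (1 - c2) ** 2)
        - 2 * ccc ** 4 * u2 * u2 / (r * r * (1 - c2) ** 2)
    ) / (n - 2)
    se = math.sqrt(max(0.0, se2))
    zc = stats.norm.ppf(0.5 + ci_level / 2.0)
    lo, hi = math.tanh(z - zc * se), math.tanh(z + zc * se)
    return float(ccc), (float(lo), float(hi))


def relative_measurement_error(device, gold) -> float:
    """Mean absolute relative measurement error, in percent of the gold score."""
    x, y = _paired_arrays(device, gold, 1)
    if np.any(y == 0):
        raise UndefinedStatisticError("relative error undefined for a zero gold score")
    return float(np.mean(100.0 * np.abs(x - y) / np.abs(y)))


def bland_altman(device, gold) -> tuple[float, float, float, float]:
    """Mean difference (device - gold), SD of differences (n-1 denominator)
    and the 95% limits of agreement mean +/- 1.96*SD."""
    x, y = _paired_arrays(device, gold, 2)
    d = x - y
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    return mean_diff, sd_diff, mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff


# ---------------------------------------------------------------------------
# reliability


def _wide_scores(rm: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long (subject, session, score) table to subjects x sessions,
    keeping complete cases only."""
    for col in ("subject", "session", "score"):
        if col not in rm.columns:
            raise InvalidInputError(f"repeated-measures table lacks column {col!r}")
    wide = rm.pivot_table(index="subject", columns="session", values="score", aggfunc="first")
    wide = wide.dropna(axis=0, how="any")
    return wide


def icc_2_1(rm: pd.DataFrame, ci_level: float = 0.95) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rating.

    ANOVA (Shrout-Fleiss) estimator on the complete-case subjects x
    sessions table:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR/MSC/MSE the between-subject, between-session and residual mean
    squares.  The confidence bounds are the standard F-distribution bounds
    with a Satterthwaite df for the session/error mixture.  Variance
    components (sigma^2_between = (MSR - MSE)/k, sigma^2_error = MSE) are
    returned so SEM can be derived.
    """
    wide = _wide_scores(rm)
    n, k = wide.shape
    if n < 2 or k < 2:
        raise DegenerateDesignError(
            f"ICC needs >= 2 subjects and >= 2 sessions (complete cases: {n} x {k})"
        )
    x = wide.to_numpy(dtype=float)
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(0.0, sse / ((n - 1) * (k - 1)))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 0.0

    # F-based CI (two-way random, absolute agreement, single measurement)
    alpha = 1.0 - ci_level
    if mse == 0 and msc <= mse:
        ci = (icc, icc)
    else:
        a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if not np.isfinite(a):
            ci = (1.0, 1.0)
        else:
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
            v = num / den if den > 0 else k - 1.0
            f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
            f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
            lower = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            upper = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
            ci = (float(lower), float(upper))
    return IccResult(
        icc=float(icc),
        ci=ci,
        var_between=float(max(0.0, (msr - mse) / k)),
        var_error=float(mse),
        msr=float(msr),
        msc=float(msc),
        mse=float(mse),
        n=n,
        k=k,
    )


def icc_mixed_adjusted(
    rm: pd.DataFrame,
    covariates: Sequence[str] = ("age", "bmi", "phone_brand"),
) -> tuple[float, float, float]:
    """Covariate-adjusted ICC from a linear mixed model.

    Fits score ~ covariates with a subject random intercept by REML and
    returns (icc_adj, var_between, var_error) with
    icc_adj = var_between / (var_between + var_error).  Tolerates
    unbalanced designs; categorical covariates are handled via patsy
    ``C()`` coding.
    """
    import statsmodels.formula.api as smf

    df = rm.dropna(subset=["subject", "session", "score", *covariates]).copy()
    counts = df.groupby("subject")["session"].nunique()
    if len(counts) < 2 or counts.max() < 2:
        raise DegenerateDesignError(
            "adjusted ICC needs >= 2 subjects and repeated sessions for at least one subject"
        )
    terms = []
    for c in covariates:
        if c not in df.columns:
            raise InvalidInputError(f"missing covariate column {c!r}")
        terms.append(f"C({c})" if df[c].dtype == object else c)
    formula = "score ~ " + (" + ".join(terms) if terms else "1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm(formula, df, groups=df["subject"]).fit(reml=True)
        except Exception as exc:  # singular design, LinAlgError, ...
            raise EstimationFailureError(f"mixed model failed: {exc}") from exc
    if not getattr(fit, "converged", True):
        raise EstimationFailureError("mixed model did not converge (REML)")
    var_between = float(np.asarray(fit.cov_re)[0, 0])
    var_error = float(fit.scale)
    icc_adj = var_between / (var_between + var_error)
    return float(icc_adj), var_between, var_error


def sem_mdc(
    var_error: float, grand_mean: Optional[float] = None
) -> tuple[float, float, Optional[float]]:
    """SEM, MDC and MDC% from an error variance.

    SEM = sqrt(var_error); MDC = 1.96 * sqrt(2) * SEM (the smallest
    within-person change distinguishable from measurement error at 95%
    confidence); MDC% = 100 * MDC / grand_mean when a grand mean is given.
    """
    if not (np.isfinite(var_error) and var_error >= 0):
        raise InvalidInputError("error variance must be a nonnegative number")
    sem = math.sqrt(var_error)
    mdc = 1.96 * math.sqrt(2.0) * sem
    mdc_percent = None
    if grand_mean is not None:
        if grand_mean <= 0:
            raise InvalidInputError("grand mean must be positive for MDC%")
        mdc_percent = 100.0 * mdc / grand_mean
    return sem, mdc, mdc_percent


def within_subject_cv(rm: pd.DataFrame) -> float:
    """Within-subject coefficient of variation, in percent.

    Per subject: 100 * SD(sessions) / mean(sessions); aggregated across
    subjects by root-mean-square (the natural pooling for a variance-like
    quantity).  Subjects with fewer than 2 sessions do not contribute.
    """
    wide = _wide_scores(rm)
    cvs = []
    for _, row in wide.iterrows():
        vals = row.to_numpy(dtype=float)
        if vals.size < 2:
            continue
        m = vals.mean()
        if m == 0:
            raise UndefinedStatisticError("CV undefined for a subject with zero mean score")
        cvs.append(100.0 * vals.std(ddof=1) / abs(m))
    if not cvs:
        raise InsufficientDataError("no subject has >= 2 sessions")
    return float(np.sqrt(np.mean(np.square(cvs))))


# ---------------------------------------------------------------------------
# design


def icc_sample_size(
    rho0: float, rho1: float, alpha: float = 0.05, power: float = 0.80, k: int = 2
) -> int:
    """Subjects needed to show the ICC exceeds ``rho0`` when it truly is
    ``rho1`` (Walter-Eliasziw-Donner approximation).

        theta_i = rho_i / (1 - rho_i)
        C0 = (1 + k*theta0) / (1 + k*theta1)
        n = ceil(1 + 2k (z_{alpha/2} + z_beta)^2 / ((k-1) ln(C0)^2))
    """
    if not (0 < rho0 < 1 and 0 < rho1 < 1 and 0 < alpha < 1 and 0 < power < 1 and k >= 2):
        raise InvalidInputError("sample-size spec outside its domain")
    if rho0 >= rho1:
        raise InfeasibleDesignError("rho0 must be strictly below rho1")
    theta0 = rho0 / (1.0 - rho0)
    theta1 = rho1 / (1.0 - rho1)
    c0 = (1.0 + k * theta0) / (1.0 + k * theta1)
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    n = 1.0 + 2.0 * k * z * z / ((k - 1.0) * math.log(c0) ** 2)
    return int(math.ceil(n - 1e-12))


def icc_power_simulation(
    rho0: float,
    rho1: float,
    n: int,
    k: int = 2,
    alpha: float = 0.05,
    n_sims: int = 2000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the one-way ANOVA F-test of H0: ICC <= rho0
    when the true ICC is rho1, with n subjects and k observations each.

    Scores are b_i + e_ij with Var(b) = rho1 and Var(e) = 1 - rho1; H0 is
    rejected when MSB/MSW exceeds (1 + k*theta0) * F_{1-alpha/2}(n-1, n(k-1)).
    Returns the rejection fraction.
    """
    rng = np.random.default_rng(seed)
    sb = math.sqrt(rho1)
    se = math.sqrt(1.0 - rho1)
    b = rng.normal(0.0, sb, size=(n_sims, n, 1))
    e = rng.normal(0.0, se, size=(n_sims, n, k))
    x = b + e
    row_means = x.mean(axis=2)
    grand = row_means.mean(axis=1, keepdims=True)
    msb = k * np.sum((row_means - grand) ** 2, axis=1) / (n - 1)
    msw = np.sum((x - row_means[..., None]) ** 2, axis=(1, 2)) / (n * (k - 1))
    theta0 = rho0 / (1.0 - rho0)
    crit = (1.0 + k * theta0) * stats.f.ppf(1.0 - alpha / 2.0, n - 1, n * (k - 1))
    return float(np.mean(msb / msw > crit))


# ---------------------------------------------------------------------------
# grading


_MCCALL_BANDS = [(0.9, "very high"), (0.7, "high"), (0.4, "moderate"), (0.2, "low"),
                 (0.0, "very low")]
_CCC_BANDS = [(0.95, "good"), (0.90, "moderate"), (0.70, "poor"), (0.0, "very poor")]


def grade_coefficient(value: float, scheme: str) -> str:
    """Qualitative label for a correlation-type coefficient.

    ``mccall_r``: very low (<0.2), low, moderate, high, very high (>=0.9).
    ``ccc``: very poor (<0.70), poor, moderate, good (>=0.95).
    Grading is on |value|; boundary values go to the upper band.
    """
    if not -1.0 <= value <= 1.0:
        raise InvalidInputError("coefficient must be in [-1, 1]")
    bands = {"mccall_r": _MCCALL_BANDS, "ccc": _CCC_BANDS}.get(scheme)
    if bands is None:
        raise InvalidInputError(f"unknown grading scheme {scheme!r}")
    v = abs(value)
    for cut, label in bands:
        if v >= cut:
            return label
    return bands[-1][1]


# ---------------------------------------------------------------------------
# report builders


def validity_report(pairs: pd.DataFrame, ci_level: float = 0.95) -> ValidityReport:
    """Full criterion-validity summary of a device-vs-gold paired table."""
    for col in ("device", "gold"):
        if col not in pairs.columns:
            raise InvalidInputError(f"paired table lacks column {col!r}")
    device, gold = pairs["device"], pairs["gold"]
    r, p, shapiro_p = pearson_with_normality(device, gold)
    ccc, ccc_ci = lins_ccc(device, gold, ci_level)
    rme = relative_measurement_error(device, gold)
    mean_diff, sd_diff, lo, hi = bland_altman(device, gold)
    return ValidityReport(
        pearson_r=r,
        pearson_p=p,
        shapiro_p=shapiro_p,
        ccc=ccc,
        ccc_ci=ccc_ci,
        mean_abs_rme=rme,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=lo,
        loa_high=hi,
        grade_r=grade_coefficient(r, "mccall_r"),
        grade_ccc=grade_coefficient(ccc, "ccc"),
        n=len(pairs.dropna(subset=["device", "gold"])),
    )


def reliability_report(
    rm: pd.DataFrame,
    model: str = "anova",
    covariates: Sequence[str] = ("age", "bmi", "phone_brand"),
    ci_level: float = 0.95,
) -> ReliabilityReport:
    """Full reproducibility/interpretability summary of a subject x session
    score table.

    ``model="anova"`` gives the unadjusted ICC(2,1); ``model="mixed"``
    gives the covariate-adjusted mixed-model ICC.  SEM/MDC always derive
    from the chosen model's error variance; the CV is the within-subject CV.
    """
    grand_mean = float(rm["score"].dropna().mean())
    anova = icc_2_1(rm, ci_level)
    if model == "anova":
        icc, ci = anova.icc, anova.ci
        var_between, var_error = anova.var_between, anova.var_error
    elif model == "mixed":
        icc, var_between, var_error = icc_mixed_adjusted(rm, covariates)
        ci = (float("nan"), float("nan"))
    else:
        raise InvalidInputError("model must be 'anova' or 'mixed'")
    sem, mdc, mdc_percent = sem_mdc(var_error, grand_mean)
    return ReliabilityReport(
        icc=icc,
        icc_ci=ci,
        var_between=var_between,
        var_error=var_error,
        sem=sem,
        cv=within_subject_cv(rm),
        mdc=mdc,
        mdc_percent=mdc_percent if mdc_percent is not None else float("nan"),
        grand_mean=grand_mean,
        model=model,
        n_subjects=anova.n,
        n_sessions=anova.k,
    )
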