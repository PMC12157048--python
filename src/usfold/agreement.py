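"""Method-comparison and reliability statistics.

Covers the statistics a validation study of two fat-mass methods needs:

* paired t comparison of means, with the 95% CI of the mean difference;
* Bland–Altman bias and 95% limits of agreement (bias ± 1.96·SD of the
  differences), plus the conventional proportional-bias check — the Pearson
  correlation of the paired differences against the pair means;
* Lin's concordance correlation coefficient (CCC) with McBride's strength
  classification (almost perfect > 0.99; substantial > 0.95 to 0.99; moderate
  0.90–0.95; poor < 0.90);
* OLS regression of caliper skinfolds on raw US thickness with anatomical site
  and gender covariates, with R² classified as substantial [0.75, 1.00],
  moderate [0.50, 0.75), weak [0.25, 0.50) and the standard error of
  estimation SEE = sqrt(SSE / (n − p));
* measurement-precision summaries: CV%, the duplicate-measurement technical
  error of measurement (TEM = sqrt(Σd²/2n)) and the two-way mixed,
  single-measure, consistency ICC — i.e. ICC(3,1);
* the a-priori sample size for a fixed-model multiple-regression overall
  F test via a noncentral-F power search (noncentrality λ = f²·N).

Degenerate inputs (zero variance) are reported as flagged results or raised as
:class:`~usfold.exceptions.DegenerateInputError` — never silently as NaN.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    CollinearityError,
    DegenerateInputError,
    InvalidInputError,
    NoSolutionError,
)

LOA_MULTIPLIER = 1.96


class CCCClass(str, enum.Enum):
    ALMOST_PERFECT = "almost_perfect"
    SUBSTANTIAL = "substantial"
    MODERATE = "moderate"
    POOR = "poor"


class R2Class(str, enum.Enum):
    SUBSTANTIAL = "substantial"
    MODERATE = "moderate"
    WEAK = "weak"
    BELOW_WEAK = "below_weak"


def classify_ccc(ccc: float) -> CCCClass:
    """McBride bands: poor < 0.90 ≤ moderate ≤ 0.95 < substantial ≤ 0.99 < almost perfect."""
    if ccc > 0.99:
        return CCCClass.ALMOST_PERFECT
    if ccc > 0.95:
        return CCCClass.SUBSTANTIAL
    if ccc >= 0.90:
        return CCCClass.MODERATE
    return CCCClass.POOR


def classify_r2(r2: float) -> R2Class:
    """Bands: substantial [0.75, 1], moderate [0.50, 0.75), weak [0.25, 0.50)."""
    if r2 >= 0.75:
        return R2Class.SUBSTANTIAL
    if r2 >= 0.50:
        return R2Class.MODERATE
    if r2 >= 0.25:
        return R2Class.WEAK
    return R2Class.BELOW_WEAK


# --------------------------------------------------------------------------- #
# Result containers
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class PairedComparison:
    n: int
    mean_diff: float
    t_stat: float
    p_value: float
    ci_low: float
    ci_high: float
    degenerate: bool = False  # zero variance of the differences


@dataclass(frozen=True)
class BlandAltman:
    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    trend_r: float | None  # None when the trend is undefined (flagged)
    trend_p: float | None
    trend_flag: str | None = None


@dataclass(frozen=True)
class AgreementReport:
    """Everything one method pair's agreement analysis produces."""

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    trend_r: float | None
    trend_p: float | None
    trend_flag: str | None
    ccc: float
    ccc_class: CCCClass
    t_stat: float
    t_p: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RegressionReport:
    coefficients: dict[str, float]
    r2: float
    r2_class: R2Class
    see: float
    n: int


# --------------------------------------------------------------------------- #
# Statistics
# --------------------------------------------------------------------------- #

def _paired_arrays(alt: Sequence[float], ref: Sequence[float],
                   min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(alt, dtype=float)
    r = np.asarray(ref, dtype=float)
    if a.ndim != 1 or r.ndim != 1 or a.shape != r.shape:
        raise InvalidInputError(
            f"alt/ref: must be 1-D and equal length, got {a.shape} vs {r.shape}"
        )
    if a.size < min_n:
        raise InvalidInputError(f"alt/ref: need at least {min_n} pairs, got {a.size}")
    if not (np.isfinite(a).all() and np.isfinite(r).all()):
        raise InvalidInputError("alt/ref: values must be finite (pairwise complete)")
    return a, r


def paired_comparison(alt: Sequence[float], ref: Sequence[float]) -> PairedComparison:
    """Two-sided paired t test on alt − ref with a 95% CI of the mean difference.

    Zero variance of the differences is flagged: identical sequences give
    t = 0, p = 1; a constant nonzero difference gives t = ±inf, p = 0.
    """
    a, r = _paired_arrays(alt, ref)
    d = a - r
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        p = 1.0 if mean == 0.0 else 0.0
        return PairedComparison(n, mean, t, p, mean, mean, degenerate=True)
    se = sd / math.sqrt(n)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    half = float(stats.t.ppf(0.975, df=n - 1)) * se
    return PairedComparison(n, mean, float(t), p, mean - half, mean + half)


def bland_altman(alt: Sequence[float], ref: Sequence[float],
                 loa_multiplier: float = LOA_MULTIPLIER) -> BlandAltman:
    """Bland–Altman bias, 95% limits of agreement, and proportional-bias trend.

    The trend is the Pearson correlation of (alt − ref) against (alt + ref)/2;
    it is reported as a flagged null when either the differences or the pair
    means have zero variance.
    """
    a, r = _paired_arrays(alt, ref)
    d = a - r
    m = (a + r) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    trend_r: float | None
    trend_p: float | None
    trend_flag = None
    if sd == 0.0 or float(m.std(ddof=1)) == 0.0:
        trend_r = trend_p = None
        trend_flag = ("zero variance of differences" if sd == 0.0
                      else "zero variance of pair means")
    else:
        res = stats.pearsonr(d, m)
        trend_r, trend_p = float(res.statistic), float(res.pvalue)
    return BlandAltman(
        n=d.size, bias=bias, sd_diff=sd,
        loa_lower=bias - loa_multiplier * sd,
        loa_upper=bias + loa_multiplier * sd,
        trend_r=trend_r, trend_p=trend_p, trend_flag=trend_flag,
    )


def lins_ccc(alt: Sequence[float], ref: Sequence[float]) -> tuple[float, CCCClass]:
    """Lin's concordance correlation coefficient with its McBride class.

    Uses population (1/n) moments, Lin's original estimator:
    ccc = 2·s_xy / (s_x² + s_y² + (mean_x − mean_y)²).
    """
    a, r = _paired_arrays(alt, ref)
    var_a = float(a.var())  # population (1/n) moments throughout
    var_r = float(r.var())
    if var_a == 0.0 or var_r == 0.0:
        raise DegenerateInputError(
            "lins_ccc: zero variance in "
            + ("alt" if var_a == 0.0 else "ref")
        )
    cov = float(((a - a.mean()) * (r - r.mean())).mean())
    ccc = 2.0 * cov / (var_a + var_r + (float(a.mean()) - float(r.mean())) ** 2)
    return ccc, classify_ccc(ccc)


def agreement_report(alt: Sequence[float], ref: Sequence[float],
                     loa_multiplier: float = LOA_MULTIPLIER) -> AgreementReport:
    """Full agreement analysis for one method pair (alt vs reference)."""
    ba = bland_altman(alt, ref, loa_multiplier)
    ccc, ccc_class = lins_ccc(alt, ref)
    t = paired_comparison(alt, ref)
    return AgreementReport(
        n=ba.n, bias=ba.bias, sd_diff=ba.sd_diff,
        loa_lower=ba.loa_lower, loa_upper=ba.loa_upper,
        trend_r=ba.trend_r, trend_p=ba.trend_p, trend_flag=ba.trend_flag,
        ccc=ccc, ccc_class=ccc_class,
        t_stat=t.t_stat, t_p=t.p_value, ci_low=t.ci_low, ci_high=t.ci_high,
    )


def regression_with_covariates(
    dependent: Sequence[float],
    raw_us: Sequence[float],
    site: Sequence[str] | None = None,
    gender: Sequence[str] | None = None,
    include: frozenset[str] | set[str] = frozenset(),
) -> RegressionReport:
    """OLS of caliper skinfold on raw US thickness, with optional covariates.

    ``include`` may contain ``"site"`` (two indicators against the triceps
    reference level) and/or ``"gender"`` (one indicator, male = 0). Returns
    the fitted coefficients, R² with its class, and SEE = sqrt(SSE/(n − p)).
    """
    y = np.asarray(dependent, dtype=float)
    x = np.asarray(raw_us, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise InvalidInputError("dependent/raw_us: must be 1-D and equal length")
    include = frozenset(include)
    unknown = include - {"site", "gender"}
    if unknown:
        raise InvalidInputError(f"include: unknown covariates {sorted(unknown)}")

    columns: dict[str, np.ndarray] = {"raw_us": x}
    if "site" in include:
        if site is None:
            raise InvalidInputError("site: required when 'site' is included")
        s = np.asarray(site, dtype=object)
        if s.shape != y.shape:
            raise InvalidInputError("site: length mismatch with dependent")
        bad = set(s) - {"triceps", "abdominal", "thigh"}
        if bad:
            raise InvalidInputError(f"site: unknown levels {sorted(bad)}")
        # triceps is the reference level
        columns["site_abdominal"] = (s == "abdominal").astype(float)
        columns["site_thigh"] = (s == "thigh").astype(float)
    if "gender" in include:
        if gender is None:
            raise InvalidInputError("gender: required when 'gender' is included")
        g = np.asarray(gender, dtype=object)
        if g.shape != y.shape:
            raise InvalidInputError("gender: length mismatch with dependent")
        bad = set(g) - {"M", "F"}
        if bad:
            raise InvalidInputError(f"gender: unknown levels {sorted(bad)}")
        columns["gender_F"] = (g == "F").astype(float)  # male = 0

    X = np.column_stack([np.ones_like(y)] + list(columns.values()))
    names = ["intercept"] + list(columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise CollinearityError(
            f"design matrix rank {rank} < {X.shape[1]} columns {names}; "
            "check for constant or duplicated predictors"
        )
    if float(y.std()) == 0.0:
        raise DegenerateInputError("dependent: constant (zero variance)")
    if y.size <= X.shape[1]:
        raise InvalidInputError(
            f"need more observations ({y.size}) than coefficients ({X.shape[1]}) "
            "for a residual standard error"
        )

    fit = sm.OLS(y, X).fit()
    r2 = float(fit.rsquared)
    see = float(np.sqrt(fit.ssr / fit.df_resid))
    return RegressionReport(
        coefficients=dict(zip(names, (float(b) for b in fit.params))),
        r2=r2, r2_class=classify_r2(r2), see=see, n=int(y.size),
    )


def cv_percent(replicates: Sequence[float]) -> float:
    """Coefficient of variation: sample SD / mean × 100."""
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise InvalidInputError("replicates: need at least 2 values")
    mean = float(x.mean())
    if mean == 0.0:
        raise InvalidInputError("replicates: zero mean, CV% undefined")
    return float(x.std(ddof=1)) / mean * 100.0


def tem_percent(trial1: Sequence[float], trial2: Sequence[float]) -> float:
    """Relative technical error of measurement over duplicate trials.

    TEM = sqrt(Σd²/2n) over the paired differences; %TEM = TEM / grand mean × 100.
    """
    a = np.asarray(trial1, dtype=float)
    b = np.asarray(trial2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise InvalidInputError("trial1/trial2: must be 1-D, equal length, non-empty")
    d = a - b
    tem = math.sqrt(float((d ** 2).sum()) / (2.0 * d.size))
    grand_mean = float(np.concatenate([a, b]).mean())
    if grand_mean == 0.0:
        raise InvalidInputError("trials: zero grand mean, %TEM undefined")
    return tem / grand_mean * 100.0


def icc_consistency(trial1: Sequence[float], trial2: Sequence[float]) -> float:
    """Two-way mixed, single-measure, consistency ICC — ICC(3,1).

    From the two-way ANOVA decomposition with k = 2 trials:
    ICC = (MS_subjects − MS_error) / (MS_subjects + (k − 1)·MS_error).
    """
    a, b = _paired_arrays(trial1, trial2)
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    trial_means = data.mean(axis=0)
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    if ss_subj == 0.0:
        raise DegenerateInputError("icc_consistency: zero between-subject variance")
    ss_trial = n * float(((trial_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_trial
    ms_subj = ss_subj / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err)


# --------------------------------------------------------------------------- #
# A-priori power
# --------------------------------------------------------------------------- #

def multiple_regression_power(n: int, f2: float, alpha: float,
                              n_predictors: int) -> float:
    """Power of the overall F test of a fixed-model multiple regression.

    Numerator df = n_predictors, denominator df = n − n_predictors − 1,
    noncentrality λ = f²·n (total-sample-size convention).
    """
    u = n_predictors
    v = n - n_predictors - 1
    if v < 1:
        return 0.0
    crit = stats.f.ppf(1.0 - alpha, u, v)
    return float(stats.ncf.sf(crit, u, v, f2 * n))


def required_n_multiple_regression(
    f2: float, alpha: float, power: float, n_predictors: int,
    n_cap: int = 100_000,
) -> int:
    """Smallest total N whose overall-F power reaches the target."""
    if not f2 > 0:
        raise InvalidInputError("f2: must be strictly positive")
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha: must lie in (0, 1)")
    if not 0 < power < 1:
        raise InvalidInputError("power: must lie in (0, 1)")
    if n_predictors < 1:
        raise InvalidInputError("n_predictors: must be at least 1")
    for n in range(n_predictors + 2, n_cap + 1):
        if multiple_regression_power(n, f2, alpha, n_predictors) >= power:
            return n
    raise NoSolutionError(
        f"target power {power} not reached by N = {n_cap}; "
        "the requested combination is infeasible under the iteration cap"
    )
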