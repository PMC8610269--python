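"""Group-comparison and survival statistics for the expression analysis.

Thin, contract-stable wrappers around scipy, lifelines and statsmodels:
Wilcoxon rank-sum (exact for small tie-free samples, tie-corrected normal
approximation otherwise), Kruskal-Wallis, Student's t / one-way ANOVA,
Pearson correlation, Kaplan-Meier product-limit curves with log-rank tests,
Cox proportional hazards (Efron ties) and logistic regression.  All tests
are two-sided; missing values are removed per analysis and the resulting
group sizes reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

#: largest per-group n at which the rank-sum test uses exact enumeration
EXACT_RANKSUM_MAX_N = 8


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    group_summaries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class SurvivalFit:
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    medians: dict[str, float | None] = field(default_factory=dict)
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    hr_table: pd.DataFrame | None = None
    n: int = 0
    n_events: int = 0
    converged: bool = True


def _clean(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[np.isfinite(arr)]


def _summary(name: str, v: np.ndarray) -> dict:
    return {
        name: {
            "n": int(v.size),
            "median": float(np.median(v)) if v.size else np.nan,
            "mean": float(np.mean(v)) if v.size else np.nan,
            "sd": float(np.std(v, ddof=1)) if v.size > 1 else np.nan,
        }
    }


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both groups have at most
    ``EXACT_RANKSUM_MAX_N`` observations and there are no ties; otherwise
    the normal approximation with mid-ranks and tie-corrected variance
    (no continuity correction, so identical samples give p = 1).
    """
    x, y = _clean(x), _clean(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("each group needs at least one non-missing value")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    small = max(x.size, y.size) <= EXACT_RANKSUM_MAX_N
    method = "exact" if (small and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=False)
    return TestResult(
        method=f"wilcoxon_rank_sum_{method}",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_per_group=(x.size, y.size),
        group_summaries={**_summary("x", x), **_summary("y", y)},
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis rank test across three or more groups (tie-corrected)."""
    cleaned = [_clean(g) for g in groups]
    if len(cleaned) < 3:
        raise ValueError("kruskal_wallis needs >= 3 groups; use wilcoxon_rank_sum for 2")
    if any(g.size == 0 for g in cleaned):
        raise ValueError("every group needs at least one non-missing value")
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*cleaned)
    return TestResult(
        method="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        n_per_group=tuple(g.size for g in cleaned),
        group_summaries={f"g{i}": s[f"g{i}"] for i, g in enumerate(cleaned) for s in [_summary(f"g{i}", g)]},
    )


def mean_difference_test(*groups, paired: bool = False) -> TestResult:
    """Student's t-test (one-sample on paired deltas, or two-sample) / ANOVA.

    ``paired=True`` expects a single array of within-subject differences and
    tests its mean against zero.  Three or more groups use one-way ANOVA.
    Degenerate zero-variance input yields t = 0, p = 1 when the tested mean
    difference is itself zero, and a missing p-value (with a warning)
    otherwise.
    """
    cleaned = [_clean(g) for g in groups]
    if paired:
        if len(cleaned) != 1:
            raise ValueError("paired test expects a single array of deltas")
        d = cleaned[0]
        if d.size < 2:
            raise ValueError("need >= 2 paired deltas")
        if np.std(d, ddof=1) == 0.0:
            if np.mean(d) == 0.0:
                return TestResult("paired_t", 0.0, 1.0, (d.size,), _summary("delta", d))
            warnings.warn("zero-variance deltas with nonzero mean; p undefined")
            return TestResult("paired_t", np.inf, np.nan, (d.size,), _summary("delta", d))
        stat, p = sps.ttest_1samp(d, 0.0)
        return TestResult("paired_t", float(stat), float(p), (d.size,), _summary("delta", d))

    if any(g.size < 2 for g in cleaned):
        raise ValueError("need >= 2 values per group")
    summaries: dict = {}
    for i, g in enumerate(cleaned):
        summaries.update(_summary(f"g{i}", g))
    if len(cleaned) == 2:
        x, y = cleaned
        if np.std(x, ddof=1) == 0.0 and np.std(y, ddof=1) == 0.0:
            if np.mean(x) == np.mean(y):
                return TestResult("student_t", 0.0, 1.0, (x.size, y.size), summaries)
            warnings.warn("zero variance in both groups with unequal means; p undefined")
            return TestResult("student_t", np.inf, np.nan, (x.size, y.size), summaries)
        stat, p = sps.ttest_ind(x, y, equal_var=True)
        return TestResult("student_t", float(stat), float(p), (x.size, y.size), summaries)
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.f_oneway(*cleaned)
    return TestResult("anova", float(stat), float(p), tuple(g.size for g in cleaned), summaries)


@dataclass
class CorrelationResult:
    r: float
    r2: float
    p_value: float
    n: int


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided t-based p; pairwise-complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn("zero variance; correlation undefined")
        return CorrelationResult(np.nan, np.nan, np.nan, int(x.size))
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(r) ** 2, float(p), int(x.size))


def km_fit(times, events, groups=None) -> SurvivalFit:
    """Kaplan-Meier product-limit curves, per-group medians, log-rank test.

    The median is the smallest time with S(t) <= 0.5; a group whose curve
    never reaches 0.5 has no median (reported as None, "not reached").
    With two or more groups the (multivariate) log-rank chi-square and
    p-value are computed.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValueError("survival times must be >= 0")
    if groups is None:
        groups = np.array(["all"] * times.size)
    groups = np.asarray(groups)
    keep = np.isfinite(times) & pd.notna(groups)
    times, events, groups = times[keep], events[keep], groups[keep]

    fit = SurvivalFit(n=int(times.size), n_events=int(events.sum()))
    for g in pd.unique(groups):
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(g))
        surv = kmf.survival_function_.reset_index()
        surv.columns = ["t", "S"]
        fit.km_curves[str(g)] = surv
        med = kmf.median_survival_time_
        fit.medians[str(g)] = None if np.isinf(med) else float(med)
    if len(fit.km_curves) >= 2:
        res = multivariate_logrank_test(times, groups, events)
        fit.logrank_chi2 = float(res.test_statistic)
        fit.logrank_p = float(res.p_value)
    return fit


def cox_fit(df: pd.DataFrame, duration_col: str, event_col: str, covariates: list[str]) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron tie handling) via partial likelihood.

    Returns hazard ratios with Wald 95% CIs and p-values per covariate.
    Listwise-deletes missing data; monotone likelihood (perfect separation)
    is reported as non-convergence rather than raising.
    """
    cols = [duration_col, event_col] + list(covariates)
    data = df[cols].apply(pd.to_numeric, errors="coerce").dropna()
    if data[event_col].sum() < 1:
        raise ValueError("need at least one event")
    cph = CoxPHFitter()
    fit = SurvivalFit(n=int(len(data)), n_events=int(data[event_col].sum()))
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            # default Newton precision (1e-7 on the step norm) leaves ~1e-3
            # coefficient error on very small datasets; tighten it
            cph.fit(
                data,
                duration_col=duration_col,
                event_col=event_col,
                fit_options={"precision": 1e-9},
            )
        failed = [
            w for w in caught if "failed to converge" in str(w.message).lower()
            or "complete separation" in str(w.message).lower()
        ]
        if failed:
            raise RuntimeError(str(failed[-1].message).splitlines()[0])
    except Exception as exc:  # monotone likelihood / separation
        warnings.warn(f"Cox fit did not converge: {exc}")
        fit.converged = False
        return fit
    summ = cph.summary
    fit.hr_table = pd.DataFrame(
        {
            "hr": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef lower 95%"]),
            "ci_high": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
            "coef": summ["coef"],
            "se": summ["se(coef)"],
        }
    )
    return fit


@dataclass
class LogisticFit:
    or_table: pd.DataFrame | None
    n: int
    converged: bool = True


def logistic_fit(outcome, covariates: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic regression; odds ratios with Wald 95% CIs.

    ``outcome`` is binary (0/1 or a two-level series).  Perfect separation
    is flagged as non-convergence.
    """
    y = pd.Series(outcome).reset_index(drop=True)
    if y.dtype == object or str(y.dtype) == "category":
        levels = sorted(y.dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"outcome must have exactly 2 levels, got {levels}")
        y = (y == levels[1]).astype(float)
    X = covariates.reset_index(drop=True).apply(pd.to_numeric, errors="coerce")
    data = pd.concat([y.rename("_y"), X], axis=1).dropna()
    if data["_y"].nunique() != 2:
        raise ValueError("both outcome classes must be present")
    exog = sm.add_constant(data.drop(columns="_y"))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(data["_y"], exog).fit(disp=0)
        if not model.mle_retvals.get("converged", True):
            raise RuntimeError("MLE did not converge")
    except Exception as exc:
        warnings.warn(f"logistic fit did not converge (possible separation): {exc}")
        return LogisticFit(or_table=None, n=int(len(data)), converged=False)
    ci = model.conf_int()
    table = pd.DataFrame(
        {
            "odds_ratio": np.exp(model.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p": model.pvalues,
            "coef": model.params,
            "se": model.bse,
        }
    ).drop(index="const")
    return LogisticFit(or_table=table, n=int(len(data)))
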