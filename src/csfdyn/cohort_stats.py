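"""Cohort statistics layer.

Shapiro–Wilk normality gating, classic (equal-variance) unpaired t-test,
one-way ANOVA with Sidak-adjusted pairwise comparisons, simple linear
regression, single-pass Grubbs outlier screening, and percent-change
summaries. Group summaries follow the mean ± SEM convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ContractError

__all__ = [
    "NormalityResult",
    "TestResult",
    "AnovaResult",
    "RegressionResult",
    "GrubbsResult",
    "PercentChange",
    "normality_gate",
    "unpaired_t",
    "anova_sidak",
    "sidak_adjust",
    "simple_regression",
    "grubbs_outlier",
    "grubbs_critical",
    "percent_change",
    "compare_groups",
]


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x)))


@dataclass
class NormalityResult:
    W: float
    p: float
    passed: bool
    degenerate: bool = False


def normality_gate(values) -> NormalityResult:
    """Shapiro–Wilk test; the gate passes when p >= 0.05."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ContractError(f"Shapiro–Wilk needs n >= 3, got {len(x)}")
    if len(x) > 2000:
        raise ContractError("Shapiro–Wilk not reliable for n > 2000")
    if np.ptp(x) == 0:
        return NormalityResult(W=float("nan"), p=0.0, passed=False, degenerate=True)
    W, p = stats.shapiro(x)
    return NormalityResult(W=float(W), p=float(p), passed=p >= 0.05)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float
    method: str
    group_means: list[float]
    group_sems: list[float]
    n_per_group: list[int]
    groups: list[str] = field(default_factory=list)
    p_adjusted: float | None = None


def unpaired_t(a, b, equal_var: bool = True, labels: tuple[str, str] = ("a", "b")) -> TestResult:
    """Two-sided Student's unpaired t-test (equal variances by default).

    Welch's correction is available via ``equal_var=False``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ContractError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            # identical constant groups: no evidence of difference
            return TestResult(0.0, 1.0, len(a) + len(b) - 2, "Student t (degenerate)",
                              [float(a.mean()), float(b.mean())], [0.0, 0.0],
                              [len(a), len(b)], list(labels))
        raise ContractError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else float(res.df)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(df),
        method="Student unpaired t" if equal_var else "Welch t",
        group_means=[float(a.mean()), float(b.mean())],
        group_sems=[_sem(a), _sem(b)],
        n_per_group=[len(a), len(b)],
        groups=list(labels),
    )


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiple-comparison adjustment ``1 − (1 − p)^m``."""
    if not (0 <= p <= 1):
        raise ContractError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ContractError("number of comparisons must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    comparisons: list[TestResult]


def anova_sidak(groups: dict, comparisons: list[tuple[str, str]] | None = None) -> AnovaResult:
    """One-way ANOVA followed by Sidak-adjusted pairwise t comparisons.

    ``comparisons`` defaults to all pairs of group names; the adjustment
    exponent m is the number of comparisons performed.
    """
    if len(groups) < 2:
        raise ContractError("ANOVA needs >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise ContractError(f"group {name!r} has n < 2")
    names = list(arrays)
    f, p = stats.f_oneway(*arrays.values())
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(comparisons)
    results = []
    for ga, gb in comparisons:
        tr = unpaired_t(arrays[ga], arrays[gb], labels=(ga, gb))
        tr.p_adjusted = sidak_adjust(tr.p_value, m)
        tr.method = f"pairwise t, Sidak m={m}"
        results.append(tr)
    n_total = sum(len(a) for a in arrays.values())
    return AnovaResult(
        f_statistic=float(f),
        p_value=float(p),
        df_between=len(arrays) - 1,
        df_within=n_total - len(arrays),
        comparisons=results,
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def simple_regression(x, y) -> RegressionResult:
    """OLS simple linear regression with r² and the two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ContractError("x and y must be paired")
    if len(x) < 3:
        raise ContractError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ContractError("x has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
    )


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t-distribution formula."""
    if n < 3:
        raise ContractError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2)))


@dataclass
class GrubbsResult:
    index: int | None
    G: float
    G_crit: float
    alpha: float


def grubbs_outlier(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-outlier Grubbs test (at most one outlier flagged).

    ``G = max|x − mean|/sd`` is compared against the t-distribution-derived
    critical value; ties in |deviation| resolve to the first index.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ContractError("Grubbs test needs n >= 3")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return GrubbsResult(index=None, G=0.0, G_crit=grubbs_critical(len(x), alpha), alpha=alpha)
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    G = float(dev[idx] / sd)
    crit = grubbs_critical(len(x), alpha)
    return GrubbsResult(index=idx if G > crit else None, G=G, G_crit=crit, alpha=alpha)


@dataclass
class PercentChange:
    raw: float
    rounded: int


def percent_change(mean_ref: float, mean_test: float) -> PercentChange:
    """``100 (test − ref)/ref`` with half-away-from-zero integer rounding."""
    if mean_ref == 0:
        raise ContractError("reference mean must be non-zero")
    raw = 100.0 * (mean_test - mean_ref) / mean_ref
    rounded = math.floor(raw + 0.5) if raw >= 0 else math.ceil(raw - 0.5)
    return PercentChange(raw=float(raw), rounded=int(rounded))


def compare_groups(a, b, labels: tuple[str, str] = ("a", "b")) -> dict:
    """Gated two-group comparison convenience wrapper.

    Runs the Shapiro–Wilk gate on each group, then the parametric t-test
    regardless of the outcome (with a warning on gate failure) plus a
    Mann–Whitney U p-value as clearly labelled supplementary output.
    """
    gate_a = normality_gate(a)
    gate_b = normality_gate(b)
    if not (gate_a.passed and gate_b.passed):
        warnings.warn(
            "normality gate failed; parametric test reported anyway, "
            "Mann-Whitney supplied as supplementary (non-standard) output",
            stacklevel=2,
        )
    t_res = unpaired_t(a, b, labels=labels)
    mw = stats.mannwhitneyu(a, b, alternative="two-sided")
    pc = percent_change(float(np.mean(a)), float(np.mean(b)))
    return {
        "normality": {labels[0]: gate_a, labels[1]: gate_b},
        "t_test": t_res,
        "mannwhitney_p_supplementary": float(mw.pvalue),
        "percent_change": pc,
    }
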