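"""Normality-gated selection of two-tailed statistical comparisons.

The gate mirrors common practice in behavioural physiology: the relevant
quantity is first tested with Shapiro-Wilk; a parametric test (paired or
unpaired t, repeated-measures ANOVA) is used when normality is not
rejected, a rank test (Wilcoxon signed-rank, Mann-Whitney, Friedman)
otherwise. Every decision is recorded in a trace so the chosen test can be
audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from arcpipe.errors import ConfigurationError, DegenerateInputError

DESIGNS = ("paired_two", "unpaired_two", "repeated_k", "factorial_two_way")


@dataclass(frozen=True)
class ComparisonDesign:
    """Comparison structure plus the alpha used by the normality gate."""

    structure: str
    alpha_normality: float = 0.05

    def __post_init__(self) -> None:
        if self.structure not in DESIGNS:
            raise ConfigurationError(f"unknown design {self.structure!r}; known: {DESIGNS}")
        if not (0.0 < self.alpha_normality < 1.0):
            raise ConfigurationError("alpha_normality must be in (0, 1)")


@dataclass
class StatResult:
    """Chosen test, two-tailed p, and the normality-gate decision trace."""

    test_name: str
    statistic: float
    pvalue: float
    n: tuple[int, ...]
    normality_pvalues: dict[str, float] = field(default_factory=dict)
    decision_trace: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "n": list(self.n),
            "normality_pvalues": self.normality_pvalues,
            "decision_trace": self.decision_trace,
        }


def _shapiro(x: np.ndarray, label: str, trace: list[str], alpha: float,
             pvals: dict[str, float]) -> bool:
    """Shapiro-Wilk; returns True when normality is NOT rejected."""
    if len(x) < 3:
        raise ConfigurationError("Shapiro-Wilk needs at least 3 observations")
    p = float(scipy.stats.shapiro(x).pvalue)
    pvals[label] = p
    normal = p >= alpha
    trace.append(
        f"shapiro({label}): p={p:.4g} -> {'normal' if normal else 'non-normal'}"
        f" at alpha={alpha}"
    )
    return normal


def select_and_run(data, design: ComparisonDesign) -> StatResult:
    """Gate on Shapiro-Wilk, then run the matching two-tailed comparison.

    ``data`` is a pair of equal-length arrays for ``paired_two``, a pair of
    arrays for ``unpaired_two``, a subject x condition matrix for
    ``repeated_k``, or a tidy frame (columns ``value``, ``factor_a``,
    ``factor_b``) for ``factorial_two_way`` (which runs a two-way ANOVA
    without a gate; no standard rank-based equivalent exists).
    """
    trace: list[str] = []
    pvals: dict[str, float] = {}
    alpha = design.alpha_normality

    if design.structure == "paired_two":
        x, y = (np.asarray(a, dtype=float) for a in data)
        if len(x) != len(y):
            raise ConfigurationError("paired design needs equal-length arrays")
        diffs = x - y
        if np.all(diffs == 0):
            raise DegenerateInputError("all paired differences are zero")
        normal = _shapiro(diffs, "differences", trace, alpha, pvals)
        if normal:
            res = scipy.stats.ttest_rel(x, y)
            name = "paired_t"
        else:
            method = "exact" if len(diffs) <= 25 else "approx"
            res = scipy.stats.wilcoxon(x, y, correction=(method == "approx"),
                                       method=method)
            name = "wilcoxon_signed_rank"
        trace.append(f"selected {name}")
        return StatResult(name, float(res.statistic), float(res.pvalue),
                          (len(x),), pvals, trace)

    if design.structure == "unpaired_two":
        x, y = (np.asarray(a, dtype=float) for a in data)
        normal = _shapiro(x, "group1", trace, alpha, pvals)
        normal &= _shapiro(y, "group2", trace, alpha, pvals)
        if normal:
            res = scipy.stats.ttest_ind(x, y)
            name = "student_t"
        else:  # either group non-normal -> rank test
            res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
            name = "mann_whitney"
        trace.append(f"selected {name}")
        return StatResult(name, float(res.statistic), float(res.pvalue),
                          (len(x), len(y)), pvals, trace)

    if design.structure == "repeated_k":
        mat = np.asarray(data, dtype=float)
        if mat.ndim != 2 or mat.shape[1] < 2:
            raise ConfigurationError("repeated_k needs a subject x condition matrix")
        if np.isnan(mat).any():
            raise ConfigurationError("missing cells are not imputed")
        normal = all(
            _shapiro(mat[:, j], f"condition{j}", trace, alpha, pvals)
            for j in range(mat.shape[1])
        )
        if normal:
            from statsmodels.stats.anova import AnovaRM

            n_sub, k = mat.shape
            long = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(n_sub), k),
                    "condition": np.tile(np.arange(k), n_sub),
                    "value": mat.ravel(),
                }
            )
            table = AnovaRM(long, "value", "subject", within=["condition"]).fit().anova_table
            trace.append("selected repeated_measures_anova")
            return StatResult(
                "repeated_measures_anova",
                float(table["F Value"].iloc[0]),
                float(table["Pr > F"].iloc[0]),
                (n_sub,), pvals, trace,
            )
        trace.append("selected friedman")
        fr = friedman_test(mat)
        fr.normality_pvalues = pvals
        fr.decision_trace = trace + fr.decision_trace
        return fr

    # factorial_two_way
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(data)
    for col in ("value", "factor_a", "factor_b"):
        if col not in df.columns:
            raise ConfigurationError("factorial design needs value/factor_a/factor_b")
    model = smf.ols("value ~ C(factor_a) * C(factor_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    inter = "C(factor_a):C(factor_b)"
    trace.append("selected two_way_anova (no gate: no rank-based equivalent)")
    return StatResult(
        "two_way_anova",
        float(table.loc[inter, "F"]),
        float(table.loc[inter, "PR(>F)"]),
        (len(df),), pvals, trace,
        extra={"anova_table": table},
    )


def friedman_test(matrix) -> StatResult:
    """Friedman chi-square from within-subject midranks, asymptotic p.

    Uses the tie-robust form
    ``chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (sum_ij r_ij^2 - n k (k+1)^2 / 4)``
    where ``r_ij`` are midranks within each subject and ``R_j`` the column
    rank sums. Identical conditions give statistic 0 and p = 1.
    """
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2:
        raise ConfigurationError("need a subject x condition matrix")
    n, k = mat.shape
    if k < 2 or n < 2:
        raise ConfigurationError("need >= 2 conditions and >= 2 subjects")
    if np.isnan(mat).any():
        raise ConfigurationError("missing cells are not imputed")
    ranks = np.apply_along_axis(scipy.stats.rankdata, 1, mat)  # midranks
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    den = float((ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0)
    if den == 0:  # every subject has all-tied conditions
        stat, p = 0.0, 1.0
    else:
        stat = num / den
        p = float(scipy.stats.chi2.sf(stat, df=k - 1))
    return StatResult(
        "friedman", stat, p, (n,), {},
        [f"friedman on {n} subjects x {k} conditions"],
    )
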