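"""UMI-threshold expression calls, exact co-expression tests and
co-localization percentages.

A cell is called positive for a gene when at least ``min_umi`` unique
molecular identifiers were detected (default 2). Pairwise association is
tested with a two-tailed Fisher exact test computed in exact rational
arithmetic; co-localization is summarised as the percentage of
reference-positive cells that are also query-positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from arcpipe.errors import ConfigurationError, DegenerateInputError


@dataclass
class CallMatrix:
    """Boolean cell x gene expression calls at a UMI threshold."""

    calls: pd.DataFrame  # bool, cells x genes
    min_umi: int

    def __post_init__(self) -> None:
        if self.calls.dtypes.map(lambda d: d != bool).any():
            self.calls = self.calls.astype(bool)

    def rate(self, gene: str) -> float:
        return float(self.calls[gene].mean())


def _counts_frame(counts) -> pd.DataFrame:
    """Accept AnnData, DataFrame or (array, genes) for call_expression."""
    if hasattr(counts, "X"):  # AnnData
        return pd.DataFrame(
            np.asarray(counts.X), index=counts.obs_names, columns=counts.var_names
        )
    return pd.DataFrame(counts)


def call_expression(counts, min_umi: int = 2) -> CallMatrix:
    """Threshold raw counts: positive iff count >= min_umi."""
    if min_umi < 1:
        raise ConfigurationError("min_umi must be >= 1")
    df = _counts_frame(counts)
    return CallMatrix(calls=df >= min_umi, min_umi=min_umi)


@dataclass
class CoexpressionResult:
    """2x2 co-expression table with odds ratio and exact two-tailed p."""

    gene_a: str
    gene_b: str
    n_pp: int  # A+ B+
    n_pn: int  # A+ B-
    n_np: int  # A- B+
    n_nn: int  # A- B-
    odds_ratio: float
    pvalue: float
    method: str
    degenerate: bool = False
    haldane_corrected: bool = False

    @property
    def table(self) -> tuple[int, int, int, int]:
        return (self.n_pp, self.n_pn, self.n_np, self.n_nn)


def exact_fisher_two_tailed(
    a: int, b: int, c: int, d: int, method: str = "point_prob"
) -> float:
    """Two-tailed Fisher exact p for table [[a, b], [c, d]].

    Computed in exact rational arithmetic over the hypergeometric support
    with both margins fixed. ``point_prob`` (default) sums the
    probabilities of all tables no more likely than the observed one;
    ``doubling`` doubles the smaller one-sided tail (capped at 1).
    Degenerate margins give p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ConfigurationError("table cells must be >= 0")
    if method not in ("point_prob", "doubling"):
        raise ConfigurationError(f"unknown two-tailed method {method!r}")
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    if row1 == 0 or row2 == 0 or col1 == 0 or col1 == n:
        return 1.0
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    if n <= 500:
        # exact rational arithmetic over the whole support
        denom = math.comb(n, col1)
        pmf = {
            x: Fraction(math.comb(row1, x) * math.comb(row2, col1 - x), denom)
            for x in range(lo, hi + 1)
        }
        p_obs = pmf[a]
        if method == "point_prob":
            p = sum(px for px in pmf.values() if px <= p_obs)
        else:
            lower = sum(pmf[x] for x in range(lo, a + 1))
            upper = sum(pmf[x] for x in range(a, hi + 1))
            p = min(Fraction(1), 2 * min(lower, upper))
        return float(min(p, Fraction(1)))
    # large tables: log-space hypergeometric mass with a relative guard
    # against ties at the observed probability
    from scipy.stats import hypergeom

    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, n, row1, col1)
    log_obs = float(hypergeom.logpmf(a, n, row1, col1))
    if method == "point_prob":
        sel = logpmf <= log_obs + 1e-9
        p = float(np.exp(logpmf[sel]).sum())
    else:
        pmf = np.exp(logpmf)
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = 2.0 * min(lower, upper)
    return float(min(p, 1.0))


def fisher_coexpression(
    calls: CallMatrix, gene_a: str, gene_b: str, method: str = "point_prob"
) -> CoexpressionResult:
    """Exact two-tailed test of association between two genes' calls.

    A degenerate margin (a gene never or always called) yields p = 1 with
    the ``degenerate`` flag set. The sample odds ratio uses the Haldane
    0.5-per-cell correction (and flags it) when any cell is zero.
    """
    for g in (gene_a, gene_b):
        if g not in calls.calls.columns:
            raise ConfigurationError(f"gene {g!r} absent from call matrix")
    ca = calls.calls[gene_a].to_numpy()
    cb = calls.calls[gene_b].to_numpy()
    a = int((ca & cb).sum())
    b = int((ca & ~cb).sum())
    c = int((~ca & cb).sum())
    d = int((~ca & ~cb).sum())
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    haldane = min(a, b, c, d) == 0
    if haldane:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    p = 1.0 if degenerate else exact_fisher_two_tailed(a, b, c, d, method)
    return CoexpressionResult(
        gene_a=gene_a, gene_b=gene_b, n_pp=a, n_pn=b, n_np=c, n_nn=d,
        odds_ratio=float(odds), pvalue=p, method=method,
        degenerate=degenerate, haldane_corrected=haldane,
    )


@dataclass
class ColocSummary:
    """Percent of reference-positive cells positive for each query gene."""

    reference: str
    n_reference: int
    percentages: dict[str, float]  # query gene -> percent in [0, 100]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "query": list(self.percentages),
                "percent": [round(v, 1) for v in self.percentages.values()],
                "n_reference": self.n_reference,
            }
        )


def coloc_percent(
    calls: CallMatrix, reference: str, queries: Sequence[str]
) -> ColocSummary:
    """100 * |ref+ & query+| / |ref+| for each query gene."""
    ref = calls.calls[reference].to_numpy()
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise DegenerateInputError(f"no {reference!r}-positive cells")
    pct = {
        q: 100.0 * float((ref & calls.calls[q].to_numpy()).sum()) / n_ref
        for q in queries
    }
    return ColocSummary(reference=reference, n_reference=n_ref, percentages=pct)


def triple_negative_fraction(
    calls: CallMatrix,
    ref_pair: tuple[str, str] = ("Lepr", "Bnc2"),
    markers: Sequence[str] = ("Agrp", "Npy", "Pomc"),
) -> float:
    """Percent of double-reference-positive cells negative for every marker.

    E.g. the share of Lepr+/Bnc2+ cells carrying none of Agrp/Npy/Pomc.
    """
    for g in (*ref_pair, *markers):
        if g not in calls.calls.columns:
            raise ConfigurationError(f"gene {g!r} absent from call matrix")
    ref = calls.calls[ref_pair[0]].to_numpy() & calls.calls[ref_pair[1]].to_numpy()
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise DegenerateInputError("no double-reference-positive cells")
    marker_pos = np.zeros(len(ref), dtype=bool)
    for m in markers:
        marker_pos |= calls.calls[m].to_numpy()
    n_clean = int((ref & ~marker_pos).sum())
    return 100.0 * n_clean / n_ref


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values for optional panel-wide screens."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues), method="fdr_bh")[1]
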