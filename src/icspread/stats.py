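"""Group-level comparisons of spread, tips, and dynamic range.

Two-way ANOVA (Type II sums of squares, suited to unbalanced designs)
with subsequent Tukey HSD comparisons of least-squares means per factor,
mirroring the columns of standard multiple-comparison tables: predicted
(LS) mean difference, 95 % CI of the difference, and the adjusted p
value from the studentized-range distribution.  Data with a single
independent variable use a Student t-test (equal variance by default;
Welch via ``equal_var=False``).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


class StatsError(ValueError):
    """Malformed or insufficient data for the requested test."""


def significance_stars(p: float) -> str:
    """Conventional star coding: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize(
    df: pd.DataFrame, response: str, by: list[str] | str
) -> pd.DataFrame:
    """Mean +/- sample SD (n-1) and n per condition.

    SD is NaN (missing) for singleton groups; an empty frame is an error.
    """
    if isinstance(by, str):
        by = [by]
    if len(df) == 0:
        raise StatsError("empty table")
    g = df.groupby(by, observed=True)[response]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
    return out.reset_index()


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


def two_sample_ttest(a, b, equal_var: bool = True) -> TTestResult:
    """Two-sided two-sample t-test (Student by default, Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("need at least 2 observations per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and np.mean(a) != np.mean(b):
        raise StatsError("degenerate zero-variance samples with unequal means")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def _check_cells(df: pd.DataFrame, response: str, factors: list[str]) -> None:
    fa, fb = factors
    la = df[fa].unique()
    lb = df[fb].unique()
    if la.size < 2 or lb.size < 2:
        raise StatsError("each factor needs at least 2 levels")
    counts = df.groupby([fa, fb], observed=True)[response].count()
    for a in la:
        for b in lb:
            if (a, b) not in counts.index or counts.loc[(a, b)] == 0:
                raise StatsError(f"empty cell ({a}, {b})")


@lru_cache(maxsize=256)
def _q_crit(alpha: float, k: int, dfr: float) -> float:
    return float(sps.studentized_range.ppf(1.0 - alpha, k, dfr))


def two_way_anova(
    df: pd.DataFrame,
    response: str,
    factors: list[str],
    include_interaction: bool = True,
):
    """Two-way ANOVA with Type II sums of squares.

    Returns ``(anova_table, fitted_model)``; suited to unbalanced
    designs (on balanced data Type II coincides with the textbook
    decomposition).
    """
    if len(factors) != 2:
        raise StatsError("exactly two factors required")
    fa, fb = factors
    for col in (response, fa, fb):
        if col not in df.columns:
            raise StatsError(f"column {col!r} not in table")
    data = df[[response, fa, fb]].dropna()
    _check_cells(data, response, factors)

    op = "*" if include_interaction else "+"
    formula = f"Q('{response}') ~ C(Q('{fa}')) {op} C(Q('{fb}'))"
    model = smf.ols(formula, data=data).fit()
    table = anova_lm(model, typ=2)
    table = table.rename(
        index=lambda s: s.replace(f"C(Q('{fa}'))", fa).replace(
            f"C(Q('{fb}'))", fb
        ).replace(":", " x ")
    )
    return table, model


def anova_tukey(
    df: pd.DataFrame,
    response: str,
    factors: list[str],
    alpha: float = 0.05,
    include_interaction: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA with Tukey HSD on least-squares means.

    Returns ``(anova_table, comparisons)``.  The ANOVA uses Type II sums
    of squares; comparisons are per factor, between LS means (cell means
    averaged over the other factor's levels), with the Tukey-Kramer
    standard error for unbalanced cells and residual df from the full
    model.
    """
    fa, fb = factors
    data = df[[response, fa, fb]].dropna()
    table, model = two_way_anova(
        data, response, factors, include_interaction=include_interaction
    )

    mse = float(model.mse_resid)
    dfr = float(model.df_resid)
    cell_means = data.groupby([fa, fb], observed=True)[response].mean()
    cell_n = data.groupby([fa, fb], observed=True)[response].count()

    rows = []
    for factor, other in ((fa, fb), (fb, fa)):
        lv = list(pd.unique(data[factor]))
        lv_other = list(pd.unique(data[other]))
        k = len(lv)
        for g1, g2 in combinations(lv, 2):
            def _ls(g):
                if factor == fa:
                    return np.mean([cell_means.loc[(g, o)] for o in lv_other])
                return np.mean([cell_means.loc[(o, g)] for o in lv_other])

            def _invn(g):
                if factor == fa:
                    return sum(1.0 / cell_n.loc[(g, o)] for o in lv_other)
                return sum(1.0 / cell_n.loc[(o, g)] for o in lv_other)

            diff = float(_ls(g1) - _ls(g2))
            b = len(lv_other)
            se = np.sqrt(mse / b**2 * (_invn(g1) + _invn(g2)))
            if se == 0:
                q_obs = 0.0 if diff == 0 else np.inf
            else:
                q_obs = abs(diff) * np.sqrt(2.0) / se
            p_adj = float(sps.studentized_range.sf(q_obs, k, dfr))
            p_adj = min(1.0, p_adj)
            p_unadj = float(2.0 * sps.t.sf(abs(diff) / se, dfr)) if se > 0 else (
                1.0 if diff == 0 else 0.0
            )
            half = _q_crit(alpha, k, dfr) * se / np.sqrt(2.0)
            rows.append(
                dict(
                    factor=factor,
                    group_a=g1,
                    group_b=g2,
                    ls_mean_diff=diff,
                    ci_low=diff - half,
                    ci_high=diff + half,
                    p_adj=p_adj,
                    p_unadj=min(1.0, p_unadj),
                    summary=significance_stars(p_adj),
                )
            )
    comparisons = pd.DataFrame(rows)
    return table, comparisons
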