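"""Statistical comparisons for transport-profile tables.

Means are compared by one-way ANOVA with Tukey's HSD post hoc; crossed
neurite-type x culture-day designs use two-way ANOVA with interaction
(Type II sums of squares, since per-day particle counts are unbalanced);
distributions are compared with the two-sample Kolmogorov-Smirnov test;
and the relative contribution of velocity vs. duration to net velocity is
read from standardized (beta) coefficients of a multiple regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupComparisonResult",
    "RegressionResult",
    "oneway_anova_tukey",
    "twoway_anova",
    "ks_two_sample",
    "regression_standardized",
    "cumulative_histogram",
]


class DegenerateDataError(ValueError):
    """All observations identical: test statistic undefined."""


@dataclass
class GroupComparisonResult:
    test: str
    factor_levels: list
    statistic: float
    p_value: float
    posthoc: dict[tuple, float] = field(default_factory=dict)
    alpha: float = 0.05
    # two-way extras: per-term F and p
    terms: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class RegressionResult:
    dependent: str
    betas: dict[str, float]
    r_squared: float
    n: int

    @property
    def dominant_predictor(self) -> str:
        return max(self.betas, key=lambda k: abs(self.betas[k]))


def oneway_anova_tukey(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> GroupComparisonResult:
    """Omnibus one-way ANOVA plus Tukey HSD adjusted pairwise p-values."""
    if len(groups) < 2:
        raise ValueError("need >= 2 factor levels")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if all(len(v) < 2 for v in arrays.values()):
        raise ValueError("need >= 2 observations in at least one level")
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all observations identical")

    f_stat, p = scipy.stats.f_oneway(*arrays.values())

    values = pooled
    labels = np.concatenate([np.full(len(v), k) for k, v in arrays.items()])
    tuk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    posthoc = {}
    res = tuk.summary().data[1:]
    for row in res:
        posthoc[(str(row[0]), str(row[1]))] = float(row[3])

    return GroupComparisonResult(
        test="oneway_anova_tukey",
        factor_levels=list(arrays),
        statistic=float(f_stat),
        p_value=float(p),
        posthoc=posthoc,
        alpha=alpha,
    )


def twoway_anova(
    df: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    interaction: bool = True,
) -> GroupComparisonResult:
    """Two-way ANOVA with Type II sums of squares on a tidy table.

    Returns per-term (F, p) for factor_a, factor_b and (optionally) the
    interaction; ``statistic``/``p_value`` carry the factor_a term for
    convenience.
    """
    if df[value].nunique() <= 1:
        raise DegenerateDataError("response has no variance")
    cells = df.groupby([factor_a, factor_b]).size()
    n_a, n_b = df[factor_a].nunique(), df[factor_b].nunique()
    if interaction and len(cells) < n_a * n_b:
        raise ValueError("empty design cell: cannot fit the interaction term")

    rhs = f"C({factor_a}) * C({factor_b})" if interaction else f"C({factor_a}) + C({factor_b})"
    model = smf.ols(f"{value} ~ {rhs}", data=df).fit()
    table = anova_lm(model, typ=2)

    terms = {}
    name_map = {
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": f"{factor_a}:{factor_b}",
    }
    for raw, nice in name_map.items():
        if raw in table.index:
            terms[nice] = (float(table.loc[raw, "F"]), float(table.loc[raw, "PR(>F)"]))

    f_a, p_a = terms[factor_a]
    return GroupComparisonResult(
        test="twoway_anova_type2",
        factor_levels=[sorted(df[factor_a].unique()), sorted(df[factor_b].unique())],
        statistic=f_a,
        p_value=p_a,
        terms=terms,
    )


def ks_two_sample(sample1: np.ndarray, sample2: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (exact or asymptotic)."""
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if len(s1) < 3 or len(s2) < 3:
        raise ValueError("each sample requires n >= 3")
    res = scipy.stats.ks_2samp(s1, s2, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def regression_standardized(
    table: pd.DataFrame, dependent: str, predictors: list[str]
) -> RegressionResult:
    """OLS on z-scored variables: standardized (beta) coefficients and r²."""
    n = len(table)
    if n <= len(predictors) + 1:
        raise ValueError("need n > number of predictors + 1")
    cols = [dependent] + predictors
    for c in cols:
        if table[c].std(ddof=1) == 0:
            raise DegenerateDataError(f"zero-variance variable: {c}")
    z = (table[cols] - table[cols].mean()) / table[cols].std(ddof=1)
    X = sm.add_constant(z[predictors].to_numpy())
    fit = sm.OLS(z[dependent].to_numpy(), X).fit()
    betas = {p: float(b) for p, b in zip(predictors, fit.params[1:])}
    return RegressionResult(
        dependent=dependent, betas=betas, r_squared=float(fit.rsquared), n=n
    )


def cumulative_histogram(
    values: np.ndarray, bin_edges: np.ndarray
) -> pd.DataFrame:
    """Empirical cumulative distribution over the given bins.

    Returns a table of (bin_edge, cumulative_fraction); the final value is
    1 (values beyond the last edge are counted there).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot build a cumulative histogram of nothing")
    edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(v, bins=edges)
    counts[-1] += np.sum(v >= edges[-1]) + np.sum(v < edges[0])
    cum = np.cumsum(counts) / v.size
    return pd.DataFrame({"bin_edge": edges[1:], "cumulative_fraction": cum})
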