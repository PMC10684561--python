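"""Group-comparison statistics shared across the pipeline.

Classical between-subjects tests with effect sizes: one-way ANOVA with
eta-squared, Student/Welch independent-samples t-tests with Cohen's d,
and a two-way factorial ANOVA for community-by-condition rating profiles.
Defaults follow the conventional reporting style for behavioral data:
pooled-variance t statistics and two-sided p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class StatsReport:
    """A single test result with the quantities typically printed.

    ``df`` is ``(df_between, df_within)`` for F tests and ``(df,)`` for
    t tests.  ``degenerate`` flags zero-variance inputs for which the
    statistic is undefined; in that case statistic/p are NaN.
    """

    test: str
    statistic: float
    df: tuple
    p_value: float
    effect_size: float
    effect_size_name: str
    group_means: dict = field(default_factory=dict)
    group_sds: dict = field(default_factory=dict)
    group_ns: dict = field(default_factory=dict)
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            self.effect_size_name: self.effect_size,
            "group_means": self.group_means,
            "group_sds": self.group_sds,
            "group_ns": self.group_ns,
            "degenerate": self.degenerate,
        }


def _group_summary(groups: Sequence[np.ndarray], names: Sequence[str]):
    means = {n: float(np.mean(g)) for n, g in zip(names, groups)}
    sds = {n: float(np.std(g, ddof=1)) for n, g in zip(names, groups)}
    ns = {n: len(g) for n, g in zip(names, groups)}
    return means, sds, ns


def one_way_anova(groups: Sequence[Sequence[float]], names: Sequence[str] | None = None) -> StatsReport:
    """Classical between-subjects one-way ANOVA.

    Parameters
    ----------
    groups
        Two or more samples of numeric values, each with >= 2 entries.
    names
        Optional group labels for the summary tables.

    Returns
    -------
    StatsReport with F, df = (k - 1, N - k), two-sided p, and classical
    eta-squared (SS_between / SS_total).
    """
    if len(groups) < 2:
        raise ValueError("one_way_anova requires at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    if names is None:
        names = [f"group_{i + 1}" for i in range(len(groups))]
    means, sds, ns = _group_summary(groups, names)

    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = float(np.sum((allv - grand) ** 2))
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = ss_total - ss_between
    k = len(groups)
    n_tot = len(allv)
    df_b, df_w = k - 1, n_tot - k

    if ss_total <= 0 or ss_within <= 0:
        return StatsReport("one_way_anova", float("nan"), (df_b, df_w), float("nan"),
                           float("nan"), "eta_squared", means, sds, ns, degenerate=True)

    f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f_stat, df_b, df_w))
    eta2 = ss_between / ss_total
    return StatsReport("one_way_anova", float(f_stat), (df_b, df_w), p,
                       float(eta2), "eta_squared", means, sds, ns)


def t_test_independent(a: Sequence[float], b: Sequence[float], pooled: bool = True,
                       names: Sequence[str] = ("a", "b")) -> StatsReport:
    """Independent-samples t-test with Cohen's d.

    ``pooled=True`` gives Student's t with df = n_a + n_b - 2 (the
    convention behind printed df like t(1998) for two 1000-replicate
    bootstrap distributions); ``pooled=False`` gives Welch's t.
    Cohen's d always uses the pooled SD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    means, sds, ns = _group_summary([a, b], names)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)

    if sp2 <= 0:
        return StatsReport("t_test_independent", float("nan"), (na + nb - 2,), float("nan"),
                           float("nan"), "cohens_d", means, sds, ns, degenerate=True)
    d = float((a.mean() - b.mean()) / np.sqrt(sp2))
    if pooled:
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
        p = float(2 * sps.t.sf(abs(t), df))
        return StatsReport("t_test_independent", float(t), (df,), p, d, "cohens_d",
                           means, sds, ns)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite df
    df = (va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return StatsReport("t_test_welch", float(t), (float(df),), float(p), d, "cohens_d",
                       means, sds, ns)


def two_way_anova(data: pd.DataFrame, response: str, factor_a: str, factor_b: str) -> dict[str, StatsReport]:
    """Two-way between-subjects factorial ANOVA (type-II sums of squares).

    Returns one StatsReport per effect (both main effects and the
    interaction), each with classical eta-squared (SS_effect / SS_total).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[response, factor_a, factor_b]].copy()
    if df[response].nunique() <= 1:
        na = df[factor_a].nunique() - 1
        nb = df[factor_b].nunique() - 1
        out = {}
        for name, d in [(factor_a, na), (factor_b, nb), (f"{factor_a}:{factor_b}", na * nb)]:
            out[name] = StatsReport("two_way_anova", float("nan"), (d, 0), float("nan"),
                                    float("nan"), "eta_squared", degenerate=True)
        return out
    model = smf.ols(f"{response} ~ C({factor_a}) * C({factor_b})", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_total = float(table["sum_sq"].sum())
    df_resid = int(table.loc["Residual", "df"])
    out: dict[str, StatsReport] = {}
    rename = {
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": f"{factor_a}:{factor_b}",
    }
    for row, name in rename.items():
        ss = float(table.loc[row, "sum_sq"])
        dfe = int(table.loc[row, "df"])
        out[name] = StatsReport(
            "two_way_anova", float(table.loc[row, "F"]), (dfe, df_resid),
            float(table.loc[row, "PR(>F)"]), ss / ss_total, "eta_squared")
    return out
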