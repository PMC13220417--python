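"""Group-comparison statistics for behavioural and electrophysiological metrics.

One-way ANOVA with Tukey HSD post-hoc tests for single-timepoint metrics
(band power, modulation index, PLV, fluorescence intensity), repeated-
measures / mixed ANOVA for day-indexed designs (water-maze learning
curves), t and F tests reconstructed from printed summary statistics
(mean +/- SD, n), and box-plot summaries (median, IQR, 1.5*IQR whiskers).

Group tables are plain pandas DataFrames with columns ``group``,
``subject``, ``value`` and, for within-subject designs, a time column
(default ``day``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, ParameterError

REQUIRED_COLUMNS = ("group", "subject", "value")


def significance_stars(p: float) -> str:
    """Conventional star coding: p<0.05 *, p<0.01 **, p<0.001 ***."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class StatResult:
    """Outcome of a group-comparison test."""

    test_name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    stars: str = ""
    pairwise: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise DataError(f"p-value {self.p_value} outside [0, 1]")
        if not self.stars:
            self.stars = significance_stars(self.p_value)


@dataclass
class BoxStats:
    """Box-plot summary: median, quartiles, 1.5*IQR whiskers, outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise DataError(f"group table missing required column {col!r}")
    if table["group"].nunique() < 2:
        raise DataError("need at least 2 groups")
    return table


def one_way_anova_tukey(table: pd.DataFrame) -> StatResult:
    """One-way ANOVA across groups followed by Tukey HSD pairwise tests."""
    table = _validate_table(table)
    groups = {g: sub["value"].to_numpy(dtype=float)
              for g, sub in table.groupby("group", sort=True)}
    for g, vals in groups.items():
        if len(vals) < 2:
            raise DataError(f"group {g!r} has fewer than 2 observations")
    f_stat, p = sps.f_oneway(*groups.values())
    k = len(groups)
    n_total = sum(len(v) for v in groups.values())

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(table["value"].to_numpy(dtype=float),
                           table["group"].to_numpy(), alpha=0.05)
    pairwise = pd.DataFrame(
        data=tk.summary().data[1:], columns=tk.summary().data[0]
    )
    pairwise["stars"] = [significance_stars(p_) for p_ in pairwise["p-adj"]]
    return StatResult(
        test_name="one_way_anova_tukey",
        statistic=float(f_stat),
        df=(float(k - 1), float(n_total - k)),
        p_value=float(p),
        pairwise=pairwise,
    )


def repeated_measures_anova(
    table: pd.DataFrame, within: str = "day", correction: bool = False
) -> StatResult:
    """Repeated-measures (or mixed, if several groups) ANOVA on a balanced
    subject x timepoint grid.

    Returns the within-subject (time) effect; for multi-group tables the
    group and interaction effects are stored in ``extras``.  Greenhouse-
    Geisser correction is available via ``correction=True``.
    """
    for col in ("subject", "value", within):
        if col not in table.columns:
            raise DataError(f"table missing required column {col!r}")
    if table["subject"].nunique() < 2:
        raise DataError("repeated-measures ANOVA needs at least 2 subjects")
    pivot = table.pivot_table(index="subject", columns=within, values="value",
                              aggfunc="first")
    na = pivot.isna().to_numpy()
    if na.any():
        missing = [(pivot.index[i], pivot.columns[j])
                   for i, j in np.argwhere(na)]
        raise DataError(f"missing cells for (subject, {within}): {missing[:5]}")

    if float(pivot.var(axis=1).max()) == 0.0:
        # every subject is flat across timepoints: no time effect (F = 0/0 -> 0)
        return StatResult(
            test_name="repeated_measures_anova",
            statistic=0.0,
            df=(float(pivot.shape[1] - 1),
                float((pivot.shape[0] - 1) * (pivot.shape[1] - 1))),
            p_value=1.0,
            stars="ns",
        )

    import pingouin as pg

    multi_group = "group" in table.columns and table["group"].nunique() > 1
    if multi_group:
        aov = pg.mixed_anova(data=table, dv="value", within=within,
                             subject="subject", between="group",
                             correction=correction)
        time_row = aov[aov["Source"] == within].iloc[0]
        extras = {"anova_table": aov}
        for src in ("group", "Interaction"):
            rows = aov[aov["Source"] == src]
            if len(rows):
                extras[f"F_{src.lower()}"] = float(rows.iloc[0]["F"])
                extras[f"p_{src.lower()}"] = float(rows.iloc[0]["p_unc"])
        df1 = float(time_row["DF1"])
        df2 = float(time_row["DF2"])
        name = "mixed_anova"
    else:
        aov = pg.rm_anova(data=table, dv="value", within=within,
                          subject="subject", correction=correction,
                          detailed=True)
        time_row = aov[aov["Source"] == within].iloc[0]
        extras = {"anova_table": aov}
        df1 = float(time_row["DF"])
        df2 = float(aov[aov["Source"] == "Error"].iloc[0]["DF"])
        name = "repeated_measures_anova"
    p_col = "p_GG_corr" if correction and "p_GG_corr" in aov.columns else "p_unc"
    p = float(time_row[p_col]) if pd.notna(time_row[p_col]) else float("nan")
    f_stat = float(time_row["F"])
    if not np.isfinite(f_stat) and float(time_row["SS"]) <= 1e-12:
        # degenerate 0/0 case: no time effect at all
        f_stat, p = 0.0, 1.0
    return StatResult(
        test_name=name,
        statistic=f_stat,
        df=(df1, df2),
        p_value=p,
        stars=significance_stars(p) if np.isfinite(p) else "ns",
        extras=extras,
    )


def compare_from_summary(
    means: list[float], sds: list[float], ns: list[int],
    labels: list[str] | None = None,
) -> StatResult:
    """Group comparison reconstructed from printed mean +/- SD and n.

    Two groups: pooled-variance t test (Welch statistics in ``extras``).
    Three or more: one-way F from the between/within sums of squares
    implied by the summary statistics.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (len(means) == len(sds) == len(ns)):
        raise ParameterError("means, sds and ns must have equal length")
    if len(means) < 2:
        raise ParameterError("need at least 2 groups")
    if np.any(ns < 2):
        raise ParameterError("every group needs n >= 2")
    if np.any(sds < 0):
        raise ParameterError("SDs must be non-negative")
    if labels is None:
        labels = [f"g{i}" for i in range(len(means))]

    if len(means) == 2:
        t, p = sps.ttest_ind_from_stats(means[0], sds[0], ns[0],
                                        means[1], sds[1], ns[1],
                                        equal_var=True)
        tw, pw = sps.ttest_ind_from_stats(means[0], sds[0], ns[0],
                                          means[1], sds[1], ns[1],
                                          equal_var=False)
        return StatResult(
            test_name="pooled_t_from_summary",
            statistic=float(t),
            df=(float(ns.sum() - 2),),
            p_value=float(p),
            extras={"welch_t": float(tw), "welch_p": float(pw)},
        )

    n_total = ns.sum()
    k = len(means)
    grand = np.sum(ns * means) / n_total
    ss_between = np.sum(ns * (means - grand) ** 2)
    ss_within = np.sum((ns - 1) * sds**2)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        f_stat = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f_stat, df_b, df_w))
    return StatResult(
        test_name="one_way_anova_from_summary",
        statistic=float(f_stat),
        df=(float(df_b), float(df_w)),
        p_value=p,
        extras={"labels": labels},
    )


def box_stats(values) -> BoxStats:
    """Box-plot summary with linear-interpolation quartiles.

    Whiskers extend to the most extreme data points within 1.5*IQR of the
    quartiles; points beyond are listed as outliers.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise DataError("box_stats needs at least one finite value")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(values[(values < lo_fence) | (values > hi_fence)]),
    )


def pairwise_unadjusted(table: pd.DataFrame) -> pd.DataFrame:
    """Unadjusted pairwise two-sample t tests (reference for Tukey p-adj)."""
    table = _validate_table(table)
    rows = []
    for g1, g2 in combinations(sorted(table["group"].unique()), 2):
        a = table.loc[table["group"] == g1, "value"].to_numpy(dtype=float)
        b = table.loc[table["group"] == g2, "value"].to_numpy(dtype=float)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        rows.append({"group1": g1, "group2": g2, "t": t, "p": p})
    return pd.DataFrame(rows)
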