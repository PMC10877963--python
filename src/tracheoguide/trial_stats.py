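"""The trial-analysis pipeline: summary tables, omnibus ANOVA, pairwise
comparisons with multiplicity adjustment, and robustness checks.

The reporting conventions follow the bench study's analysis plan:
results as mean (SD) and median (IQR); one- or two-way ANOVA for group
differences, switching to a type-III sum-of-squares decomposition when
group sizes are unbalanced; Tukey HSD pairwise comparisons (the
Tukey-Kramer extension on unbalanced data) with Benjamini-Hochberg
adjusted p values; Levene's homogeneity test gating a Welch one-way
ANOVA; Kruskal-Wallis (and Wilcoxon rank-sum for two groups) to confirm
conclusions non-parametrically; Shapiro-Wilk per-group normality checks.
A two-tailed p < 0.05 is treated as significant throughout.

Quantiles (hence the IQR) use linear interpolation between order
statistics.  Abandoned attempts are excluded from time-to-target
summaries and counted separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ALPHA",
    "TestResult",
    "summarize",
    "omnibus",
    "type3_anova",
    "pairwise",
    "robustness",
    "bh_adjust",
    "exclude_abandoned",
]

#: Two-tailed significance level used for all branch decisions.
ALPHA = 0.05

OUTCOMES = ("time_to_target", "final_radial_distance")


@dataclass(frozen=True)
class TestResult:
    """One statistical test: name, statistic, df, p, optional adjustment."""

    test_name: str
    statistic: float
    p_value: float
    df: Optional[tuple] = None
    adjusted_p: Optional[float] = None
    groups: tuple = ()
    note: str = ""

    def __post_init__(self):
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p value outside [0, 1]: {self.p_value}")

    def to_record(self) -> dict:
        return {
            "test": self.test_name,
            "groups": "|".join(map(str, self.groups)),
            "statistic": self.statistic,
            "df": "" if self.df is None else "/".join(f"{d:g}" for d in self.df),
            "p_value": self.p_value,
            "adjusted_p": "" if self.adjusted_p is None else self.adjusted_p,
            "note": self.note,
        }


def exclude_abandoned(data: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Drop abandoned attempts from time-to-target analyses (they carry the
    censored cutoff time, not a completion time)."""
    if outcome == "time_to_target" and "abandoned" in data.columns:
        return data.loc[~data["abandoned"].astype(bool)]
    return data


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25, 75])  # linear-interpolation quantiles
    return float(q3 - q1)


def summarize(
    data: pd.DataFrame,
    outcome: str,
    by: Union[str, Sequence[str]],
    diff_between: Optional[tuple] = None,
    test: Optional[str] = None,
) -> pd.DataFrame:
    """Per-group count / mean / SD / median / IQR summary table.

    For a two-group comparison the table carries ``mean_difference`` =
    mean(first) − mean(second), where the pair is ``diff_between`` if
    given, else the two groups in order of first appearance, plus a
    p value from ``test`` ("wilcoxon" rank-sum, "anova", or None).
    Abandoned attempts are excluded from time summaries; empty groups
    yield count 0 with moments flagged as NaN.
    """
    by_cols = [by] if isinstance(by, str) else list(by)
    data = exclude_abandoned(data, outcome)

    rows = []
    order = list(dict.fromkeys(map(tuple, data[by_cols].itertuples(index=False))))
    for key in order:
        sub = data
        for col, val in zip(by_cols, key):
            sub = sub[sub[col] == val]
        vals = sub[outcome].to_numpy(dtype=float)
        row = dict(zip(by_cols, key))
        row["count"] = len(vals)
        if len(vals) == 0:
            row.update(mean=np.nan, sd=np.nan, median=np.nan, iqr=np.nan)
        else:
            row.update(
                mean=float(np.mean(vals)),
                sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                median=float(np.median(vals)),
                iqr=_iqr(vals),
            )
        rows.append(row)
    table = pd.DataFrame(rows)

    group_labels = (
        table[by_cols[0]] if len(by_cols) == 1 else table[by_cols].agg("/".join, axis=1)
    )
    if diff_between is None and len(table) == 2:
        diff_between = tuple(group_labels)
    if diff_between is not None:
        means = dict(zip(group_labels, table["mean"]))
        a, b = diff_between
        table.attrs["diff_between"] = (a, b)
        table["mean_difference"] = np.nan
        table.loc[group_labels == a, "mean_difference"] = means[a] - means[b]

        if test is not None:
            va = data.loc[group_labels_mask(data, by_cols, a), outcome].to_numpy(float)
            vb = data.loc[group_labels_mask(data, by_cols, b), outcome].to_numpy(float)
            if test == "wilcoxon":
                stat, p = sps.ranksums(va, vb)
                name = "Wilcoxon rank-sum"
            elif test == "anova":
                res = omnibus(
                    pd.DataFrame({outcome: np.concatenate([va, vb]),
                                  "_g": ["a"] * len(va) + ["b"] * len(vb)}),
                    outcome,
                    "_g",
                )
                stat, p, name = res.statistic, res.p_value, res.test_name
            else:
                raise ValueError(f"unknown test {test!r}")
            table.attrs["p_value"] = float(p)
            table.attrs["test_name"] = name
            table["p_value"] = np.nan
            table.loc[group_labels == a, "p_value"] = float(p)
    return table


def group_labels_mask(data: pd.DataFrame, by_cols: list, label) -> pd.Series:
    if len(by_cols) == 1:
        return data[by_cols[0]] == label
    combo = data[by_cols].agg("/".join, axis=1)
    return combo == label


def _is_balanced(counts: Sequence[int]) -> bool:
    return len(set(counts)) == 1


def omnibus(
    data: pd.DataFrame,
    outcome: str,
    factors: Union[str, Sequence[str]],
    interaction: bool = False,
) -> TestResult:
    """One- or two-way ANOVA for group differences.

    Balanced single-factor data take the classical decomposition (where
    type I, II and III sums of squares coincide); unbalanced or
    multi-factor data use a type-III decomposition with sum-to-zero
    contrasts, detected automatically.  Returns the (first) factor's F
    test; the full ANOVA table is attached as ``result.note`` context via
    ``omnibus.table_`` for inspection.
    """
    factor_list = [factors] if isinstance(factors, str) else list(factors)
    data = exclude_abandoned(data, outcome).copy()

    groups = [g[outcome].to_numpy(float) for _, g in data.groupby(factor_list, sort=True)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("omnibus requires >= 2 groups with >= 2 observations each")
    for name, g in data.groupby(factor_list, sort=True):
        if float(np.var(g[outcome])) == 0.0:
            raise ValueError(f"degenerate (zero-variance) group: {name}")

    counts = [len(g) for g in groups]
    balanced = _is_balanced(counts)

    if len(factor_list) == 1 and balanced and not interaction:
        f_stat, p = sps.f_oneway(*groups)
        df = (len(groups) - 1, sum(counts) - len(groups))
        return TestResult(
            test_name="one-way ANOVA (balanced; type I = III)",
            statistic=float(f_stat),
            p_value=float(p),
            df=df,
            groups=tuple(str(k) for k, _ in data.groupby(factor_list, sort=True)),
        )
    result = type3_anova(data, outcome, factor_list, interaction=interaction)
    if not balanced:
        result = TestResult(
            **{**result.__dict__, "note": "unbalanced groups"}
        )
    return result


def type3_anova(
    data: pd.DataFrame,
    outcome: str,
    factors: Union[str, Sequence[str]],
    interaction: bool = False,
) -> TestResult:
    """Type-III sum-of-squares ANOVA with sum-to-zero contrasts (without
    which the type-III decomposition is not meaningful); returns the first
    factor's F test.  On balanced single-factor data this coincides with
    the classical one-way decomposition."""
    factor_list = [factors] if isinstance(factors, str) else list(factors)
    terms = [f"C(Q('{f}'), Sum)" for f in factor_list]
    rhs = " * ".join(terms) if interaction else " + ".join(terms)
    model = smf.ols(f"Q('{outcome}') ~ {rhs}", data=data).fit()
    table = sm.stats.anova_lm(model, typ=3)
    first = f"C(Q('{factor_list[0]}'), Sum)"
    return TestResult(
        test_name="type-III ANOVA (sum-to-zero contrasts)",
        statistic=float(table.loc[first, "F"]),
        p_value=float(table.loc[first, "PR(>F)"]),
        df=(float(table.loc[first, "df"]), float(table.loc["Residual", "df"])),
        groups=tuple(str(k) for k, _ in data.groupby(factor_list, sort=True)),
        note="multi-factor" if len(factor_list) > 1 else "",
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment: p(i)·m/i on the sorted
    p values with monotone enforcement, clipped to 1."""
    rejected, adjusted, _, _ = multipletests(p_values, alpha=ALPHA, method="fdr_bh")
    return adjusted


def pairwise(data: pd.DataFrame, outcome: str, factor: str) -> pd.DataFrame:
    """All-pairs Tukey HSD with BH-adjusted p values.

    The BH family is the set of all pairwise comparisons for this outcome
    and factor.  On unbalanced data the Tukey-Kramer extension applies.
    Returns a table with group pair, mean difference, Tukey p and BH
    adjusted p; empty for fewer than two groups.
    """
    data = exclude_abandoned(data, outcome)
    levels = data[factor].unique()
    if len(levels) < 2:
        return pd.DataFrame(
            columns=["group1", "group2", "mean_difference", "p_tukey", "p_adjusted"]
        )
    res = pairwise_tukeyhsd(
        data[outcome].to_numpy(float), data[factor].to_numpy(), alpha=ALPHA
    )
    table = pd.DataFrame(
        res.summary().data[1:], columns=[c.strip() for c in res.summary().data[0]]
    )
    out = pd.DataFrame(
        {
            "group1": table["group1"],
            "group2": table["group2"],
            "mean_difference": table["meandiff"].astype(float),
            "p_tukey": np.asarray(res.pvalues, dtype=float),
        }
    )
    out["p_adjusted"] = bh_adjust(out["p_tukey"].to_numpy())
    return out


def robustness(
    data: pd.DataFrame, outcome: str, factor: str
) -> tuple[pd.DataFrame, list[str]]:
    """Distributional and robustness checks mirroring the analysis plan.

    Runs Shapiro-Wilk per group (skipped with a note for n < 3), Levene
    across groups, a Welch one-way ANOVA when Levene rejects homogeneity
    at α = 0.05, Kruskal-Wallis always, and a Wilcoxon rank-sum test for
    two-group factors.  Returns the test table and a plain-text decision
    trace of the branches taken.
    """
    import pingouin as pg

    data = exclude_abandoned(data, outcome)
    results: list[TestResult] = []
    trace: list[str] = []

    grouped = {k: g[outcome].to_numpy(float) for k, g in data.groupby(factor, sort=True)}
    levels = list(grouped)
    for name, vals in grouped.items():
        if len(vals) < 3:
            trace.append(f"Shapiro-Wilk skipped for group {name}: n={len(vals)} < 3")
            results.append(
                TestResult(
                    "Shapiro-Wilk", float("nan"), float("nan"),
                    groups=(name,), note="skipped: n < 3",
                )
            )
            continue
        w, p = sps.shapiro(vals)
        results.append(TestResult("Shapiro-Wilk", float(w), float(p), groups=(name,)))
        trace.append(
            f"Shapiro-Wilk group {name}: W={w:.4f}, p={p:.4g} "
            f"({'non-normal' if p < ALPHA else 'no evidence against normality'})"
        )

    usable = [v for v in grouped.values() if len(v) >= 2]
    lev_stat, lev_p = sps.levene(*usable)
    results.append(
        TestResult("Levene", float(lev_stat), float(lev_p), groups=tuple(levels))
    )
    if lev_p < ALPHA:
        trace.append(
            f"Levene p={lev_p:.4g} < {ALPHA}: variances heterogeneous -> Welch ANOVA"
        )
        welch = pg.welch_anova(data=data, dv=outcome, between=factor)
        p_col = "p_unc" if "p_unc" in welch.columns else "p-unc"
        results.append(
            TestResult(
                "Welch ANOVA",
                float(welch["F"].iloc[0]),
                float(welch[p_col].iloc[0]),
                df=(float(welch["ddof1"].iloc[0]), float(welch["ddof2"].iloc[0])),
                groups=tuple(levels),
            )
        )
    else:
        trace.append(
            f"Levene p={lev_p:.4g} >= {ALPHA}: homogeneity accepted, Welch branch not taken"
        )

    kw_stat, kw_p = sps.kruskal(*grouped.values())
    results.append(
        TestResult("Kruskal-Wallis", float(kw_stat), float(kw_p), groups=tuple(levels))
    )
    trace.append(f"Kruskal-Wallis H={kw_stat:.4f}, p={kw_p:.4g}")

    if len(levels) == 2:
        w_stat, w_p = sps.ranksums(*grouped.values())
        results.append(
            TestResult("Wilcoxon rank-sum", float(w_stat), float(w_p), groups=tuple(levels))
        )
        trace.append(f"Wilcoxon rank-sum (two groups): z={w_stat:.4f}, p={w_p:.4g}")

    return pd.DataFrame([r.to_record() for r in results]), trace
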