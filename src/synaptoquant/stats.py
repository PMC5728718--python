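"""Group summaries, penetrance, paralysis time courses, and significance tests.

Statistics follow common practice for this assay family: penetrance is
the fraction of animals scored diffuse with a Wilson 95% interval,
aldicarb paralysis is summarized as the fraction of animals moving per
time point averaged across plates (the plate is the replication unit),
and group comparisons use Student's t-test, one-way ANOVA, or two-way
ANOVA with Tukey's post-hoc test.  Error bars are SEM throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PenetranceResult",
    "ComparisonResult",
    "penetrance",
    "aldicarb_timecourse",
    "compare_groups",
    "significance_stars",
]

_STAR_BANDS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def significance_stars(p: float) -> str:
    """Star band for a p-value: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    for cut, stars in _STAR_BANDS:
        if p < cut:
            return stars
    return "ns"


@dataclass(frozen=True)
class PenetranceResult:
    """Fraction of animals scored diffuse, with a Wilson 95% interval."""

    proportion_diffuse: float
    ci_low: float
    ci_high: float
    n_animals: int
    n_diffuse: int

    @property
    def percent_diffuse(self) -> float:
        return 100.0 * self.proportion_diffuse


def penetrance(classifications: list[str]) -> PenetranceResult:
    """Penetrance of the diffuse phenotype over per-animal classifications."""
    if not classifications:
        raise ValueError("penetrance requires at least one scored animal")
    bad = set(classifications) - {"punctate", "diffuse"}
    if bad:
        raise ValueError(f"unrecognized phenotype labels: {sorted(bad)}")
    n = len(classifications)
    k = sum(1 for c in classifications if c == "diffuse")
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return PenetranceResult(k / n, float(lo), float(hi), n, k)


def aldicarb_timecourse(assay: pd.DataFrame) -> pd.DataFrame:
    """Fraction of animals moving per time point per condition.

    ``assay`` is long-format with columns ``condition, plate, time_min,
    n_moving, n_total`` (one row per plate per time point).  Plates are
    averaged at the plate level; SEM is across plates.
    """
    df = assay.copy()
    required = {"condition", "time_min", "n_moving", "n_total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay table lacks columns: {sorted(missing)}")
    if (df["n_total"] <= 0).any():
        raise ValueError("n_total must be positive on every plate")
    if ((df["n_moving"] < 0) | (df["n_moving"] > df["n_total"])).any():
        raise ValueError("n_moving must lie in [0, n_total]")
    df["fraction_moving"] = df["n_moving"] / df["n_total"]
    if "plate" not in df.columns:
        df["plate"] = 0
    out = (
        df.groupby(["condition", "time_min"])["fraction_moving"]
        .agg(
            fraction_moving="mean",
            sem=lambda v: float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
            n_plates="size",
        )
        .reset_index()
    )
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a group comparison."""

    design: str
    statistic: float
    df: tuple
    p_value: float
    stars: str
    pairwise: pd.DataFrame | None = None
    anova_table: pd.DataFrame | None = None


def _group_arrays(table: pd.DataFrame, group: str, value: str):
    groups = {g: sub[value].to_numpy(float) for g, sub in table.groupby(group, sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        if np.std(v) == 0 and len(groups) == 2:
            pass  # t-test handles equal-variance zero case below
    return groups


def compare_groups(
    table: pd.DataFrame,
    design: str = "two_group",
    value: str = "value",
    group: str = "genotype",
    factor2: str | None = None,
) -> ComparisonResult:
    """Compare metric values between groups.

    ``design`` selects Student's t-test (``two_group``), one-way ANOVA
    with Tukey's post-hoc (``one_way``), or two-way ANOVA on
    ``group × factor2`` with Tukey on the cell means (``two_way``).
    """
    if design == "two_group":
        groups = _group_arrays(table, group, value)
        if len(groups) != 2:
            raise ValueError("two_group design requires exactly 2 groups")
        (ga, a), (gb, b) = sorted(groups.items())
        t, p = sps.ttest_ind(a, b, equal_var=True)
        dof = a.size + b.size - 2
        return ComparisonResult("two_group", float(t), (dof,), float(p), significance_stars(p))

    if design == "one_way":
        groups = _group_arrays(table, group, value)
        arrays = [groups[g] for g in sorted(groups)]
        f, p = sps.f_oneway(*arrays)
        k = len(arrays)
        n = sum(v.size for v in arrays)
        tk = pairwise_tukeyhsd(table[value].to_numpy(float), table[group].to_numpy(str))
        pw = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        pw["stars"] = [significance_stars(q) for q in tk.pvalues]
        return ComparisonResult("one_way", float(f), (k - 1, n - k), float(p),
                                significance_stars(p), pairwise=pw)

    if design == "two_way":
        if factor2 is None:
            raise ValueError("two_way design requires factor2")
        df = table.rename(columns={value: "y", group: "fa", factor2: "fb"})
        model = ols("y ~ C(fa) * C(fb)", data=df).fit()
        tab = anova_lm(model, typ=2)
        inter = tab.loc["C(fa):C(fb)"]
        cells = (df["fa"].astype(str) + ":" + df["fb"].astype(str)).to_numpy()
        tk = pairwise_tukeyhsd(df["y"].to_numpy(float), cells)
        pw = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        pw["stars"] = [significance_stars(q) for q in tk.pvalues]
        p = float(inter["PR(>F)"])
        return ComparisonResult(
            "two_way",
            float(inter["F"]),
            (int(inter["df"]), int(tab.loc["Residual", "df"])),
            p,
            significance_stars(p),
            pairwise=pw,
            anova_table=tab,
        )

    raise ValueError(f"unknown design {design!r}")


def group_summary(table: pd.DataFrame, value: str = "value", group: str = "genotype") -> pd.DataFrame:
    """Per-group mean, SEM, and n for bar-plot style reporting."""
    return (
        table.groupby(group)[value]
        .agg(mean="mean", sem=lambda v: float(v.std(ddof=1) / np.sqrt(len(v))), n="size")
        .reset_index()
    )


def plot_group_bars(summary: pd.DataFrame, table: pd.DataFrame | None = None,
                    value: str = "value", group: str = "genotype", ax=None):
    """Bar + scatter panel with SEM error bars (figure-style group plot)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    xs = np.arange(len(summary))
    ax.bar(xs, summary["mean"], yerr=summary["sem"], capsize=3,
           color="lightgray", edgecolor="black")
    if table is not None:
        for i, g in enumerate(summary[group]):
            v = table.loc[table[group] == g, value]
            ax.plot(np.full(len(v), i) + np.random.default_rng(0).uniform(-0.15, 0.15, len(v)),
                    v, "o", ms=3, color="black", alpha=0.6)
    ax.set_xticks(xs)
    ax.set_xticklabels(summary[group], rotation=45, ha="right")
    return ax
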