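"""Gene-environment stratified comparison tables and descriptive summaries.

Participants are split into high vs low genetic-risk groups (90th
percentile of the wPRS) and, within each lifestyle/metabolic exposure
level, mean lipid levels are compared along two axes:

* axis (a): high vs low genetic risk, within each exposure level;
* axis (b): between exposure levels, within each genetic-risk group.

Trait comparisons use the Mann-Whitney U test (lipid levels are
right-skewed); categorical compositions use the Pearson chi-square test
without continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .wprs import ScoreSet


# ---------------------------------------------------------------------------
# Rank / contingency tests
# ---------------------------------------------------------------------------

def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null enumeration when the smaller sample has at most
    8 observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  Returns
    ``(U, p)`` with U counted for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if min(x.size, y.size) <= 8 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi_square_test(
    table: Sequence[Sequence[float]], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2 x k count table.

    No continuity correction by default.  Warns when any expected count
    is below 5; raises on a zero row/column marginal.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.min() < 0:
        raise ValueError("table must be a 2-D array of non-negative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(obs, correction=correction)
    if (res.expected_freq < 5).any():
        warnings.warn("expected count below 5; chi-square approximation is poor",
                      stacklevel=2)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Exposure definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Exposure:
    """One stratification variable: a cohort column and its level labels."""

    name: str
    column: str
    levels: Mapping[object, str]


def default_exposures() -> list[Exposure]:
    """The study's lifestyle/metabolic stratification variables.

    Coffee and SSB are dichotomised at none vs >= 1 cup/day, wine at none
    vs 1-3 drinks/week, obesity at BMI >= 30 (inclusive) and HbA1c at
    >= 5.7% (inclusive).
    """
    return [
        Exposure("sex", "sex", {"M": "male", "F": "female"}),
        Exposure("wine", "wine", {0: "none", 1: "1-3 drinks/week"}),
        Exposure("coffee", "coffee", {0: "none", 1: ">=1 cup/day"}),
        Exposure("obesity", "obesity", {0: "BMI<30", 1: "BMI>=30"}),
        Exposure("smoking", "smoking", {0: "non-smoker", 1: "smoker"}),
        Exposure("ssb", "ssb", {0: "none", 1: ">=1 cup/day"}),
        Exposure("hba1c", "hba1c_high", {0: "<5.7%", 1: ">=5.7%"}),
    ]


@dataclass
class StrataTable:
    """Stratified cell summaries plus the two comparison axes.

    ``cells`` has one row per (exposure, level, risk group) with n, mean
    and SD of the trait; ``comparisons`` carries the axis-(a) and
    axis-(b) Mann-Whitney p-values (NaN where a cell is empty, with the
    note column saying so).
    """

    trait: str
    cells: pd.DataFrame
    comparisons: pd.DataFrame


def build_strata_table(
    cohort: pd.DataFrame,
    scores: ScoreSet,
    trait: str,
    exposures: Sequence[Exposure] | None = None,
) -> StrataTable:
    """Cross-tabulate a lipid trait by genetic-risk group and exposures.

    Subjects with a missing exposure value form an explicit ``missing``
    level that is summarised but excluded from comparisons.  Empty cells
    mark their comparison undefined (p = NaN) rather than being dropped.
    """
    if exposures is None:
        exposures = default_exposures()
    if trait not in cohort.columns:
        raise ValueError(f"trait {trait!r} absent from cohort")
    if scores.risk_group is None:
        raise ValueError("scores must be stratified first")
    idx = cohort.index.intersection(scores.risk_group.index)
    data = cohort.loc[idx]
    group = scores.risk_group.loc[idx]

    cell_rows, comp_rows = [], []
    for exp in exposures:
        if exp.column not in data.columns:
            raise ValueError(f"exposure column {exp.column!r} absent from cohort")
        col = data[exp.column]
        level_masks: dict[str, pd.Series] = {}
        for value, label in exp.levels.items():
            level_masks[label] = col == value
        missing = ~np.logical_or.reduce([m.to_numpy() for m in level_masks.values()])
        if missing.any():
            level_masks["missing"] = pd.Series(missing, index=data.index)

        for label, mask in level_masks.items():
            for risk in ("high", "low"):
                vals = data.loc[mask & (group == risk), trait].dropna()
                cell_rows.append({
                    "exposure": exp.name, "level": label, "risk_group": risk,
                    "n": len(vals),
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sd": vals.std(ddof=1) if len(vals) >= 2 else np.nan,
                })

        defined = [lb for lb in level_masks if lb != "missing"]
        # axis (a): high vs low within each exposure level
        for label in defined:
            mask = level_masks[label]
            hi = data.loc[mask & (group == "high"), trait].dropna()
            lo = data.loc[mask & (group == "low"), trait].dropna()
            if len(hi) and len(lo):
                _, p = mann_whitney_u(hi, lo)
                note = ""
            else:
                p, note = np.nan, "undefined: empty cell"
            comp_rows.append({
                "exposure": exp.name, "axis": "a", "context": label,
                "test": "mann-whitney", "p": p, "note": note,
            })
        # axis (b): between exposure levels within each risk group
        for risk in ("high", "low"):
            if len(defined) != 2:
                comp_rows.append({
                    "exposure": exp.name, "axis": "b", "context": risk,
                    "test": "mann-whitney", "p": np.nan,
                    "note": "undefined: needs exactly 2 levels",
                })
                continue
            g0 = data.loc[level_masks[defined[0]] & (group == risk), trait].dropna()
            g1 = data.loc[level_masks[defined[1]] & (group == risk), trait].dropna()
            if len(g0) and len(g1):
                _, p = mann_whitney_u(g0, g1)
                note = ""
            else:
                p, note = np.nan, "undefined: empty cell"
            comp_rows.append({
                "exposure": exp.name, "axis": "b", "context": risk,
                "test": "mann-whitney", "p": p, "note": note,
            })

    return StrataTable(
        trait=trait,
        cells=pd.DataFrame(cell_rows),
        comparisons=pd.DataFrame(comp_rows),
    )


# ---------------------------------------------------------------------------
# Descriptive (Table-1-style) summaries
# ---------------------------------------------------------------------------

def descriptive_table(
    cohort: pd.DataFrame,
    grouping: ScoreSet | pd.Series | None = None,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Mean +/- SD and n (%) summaries, overall and by risk group.

    Continuous variables are compared between groups with the
    Mann-Whitney U test, categorical variables with the chi-square test.
    With ``grouping=None`` only the overall column is produced.
    """
    group = None
    if grouping is not None:
        group = grouping.risk_group if isinstance(grouping, ScoreSet) else grouping
        group = group.loc[cohort.index.intersection(group.index)]
        cohort = cohort.loc[group.index]

    rows = []
    for var in continuous:
        vals = pd.to_numeric(cohort[var]).dropna()
        row = {"variable": var, "level": "", "type": "continuous",
               "overall_n": len(vals), "overall_mean": vals.mean(),
               "overall_sd": vals.std(ddof=1), "overall_pct": np.nan}
        if group is not None:
            lo = vals[group.reindex(vals.index) == "low"]
            hi = vals[group.reindex(vals.index) == "high"]
            row.update(low_n=len(lo), low_mean=lo.mean(), low_sd=lo.std(ddof=1),
                       high_n=len(hi), high_mean=hi.mean(), high_sd=hi.std(ddof=1))
            if len(lo) and len(hi):
                _, p = mann_whitney_u(hi, lo)
                row.update(p=p, test="mann-whitney")
            else:
                row.update(p=np.nan, test="undefined")
        rows.append(row)
    for var in categorical:
        col = cohort[var]
        levels = sorted(col.dropna().unique(), key=str)
        n_total = col.notna().sum()
        table = None
        if group is not None:
            table = pd.crosstab(col, group)
            try:
                _, p_var = chi_square_test(table.to_numpy())
            except ValueError:
                p_var = np.nan
        for level in levels:
            mask = col == level
            row = {"variable": var, "level": str(level), "type": "categorical",
                   "overall_n": int(mask.sum()),
                   "overall_pct": 100.0 * mask.sum() / n_total,
                   "overall_mean": np.nan, "overall_sd": np.nan}
            if group is not None:
                for g in ("low", "high"):
                    gmask = group == g
                    denom = (col.notna() & gmask).sum()
                    row[f"{g}_n"] = int((mask & gmask).sum())
                    row[f"{g}_pct"] = (
                        100.0 * (mask & gmask).sum() / denom if denom else np.nan
                    )
                row.update(p=p_var, test="chi-square")
            rows.append(row)
    return pd.DataFrame(rows)
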