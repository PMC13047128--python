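"""Baseline group comparisons of ADL and the four-scale correlation matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from longmed.data_model import COVARIATE_COLUMNS, SCORE_COLUMNS, CohortPanel


class AnalysisError(ValueError):
    """The requested comparison is not computable on this panel."""


@dataclass(frozen=True)
class GroupComparison:
    """ADL (UPDRS-II) at baseline compared across levels of one covariate."""

    grouping: str
    levels: list[str]
    n: list[int]
    percent: list[float]
    means: list[float]
    sds: list[float]
    statistic: float
    p_value: float
    test: str  # "two_sample_t" or "one_way_anova"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.levels,
                "n": self.n,
                "percent": self.percent,
                "mean": self.means,
                "sd": self.sds,
            }
        )


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson correlations among rbdsq, gds15, moca, updrs2.

    Entries whose computation is undefined (zero variance, too few pairs)
    are NaN in ``r``/``p`` and flagged by name in ``undefined``.
    """

    variables: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray
    undefined: list[tuple[str, str]]
    scope: str
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)


def compare_adl_by(panel: CohortPanel, grouping: str) -> GroupComparison:
    """Equal-variance t-test (2 levels) or one-way ANOVA (>2) of baseline ADL.

    Empty levels are dropped; the test follows the number of nonempty
    levels, matching the single t/F reporting convention of baseline tables.
    """
    if grouping not in COVARIATE_COLUMNS:
        raise AnalysisError(f"unknown covariate {grouping!r}")
    base = panel.baseline().dropna(subset=[grouping, "updrs2"])
    if base.empty:
        raise AnalysisError("no baseline rows with ADL and grouping present")
    groups = [
        (str(level), sub["updrs2"].to_numpy(dtype=float))
        for level, sub in base.groupby(grouping, observed=True)
        if len(sub) > 0
    ]
    if len(groups) < 2:
        raise AnalysisError(
            f"grouping {grouping!r} has fewer than 2 nonempty levels at baseline"
        )
    values = [v for _, v in groups]
    if len(groups) == 2:
        test = "two_sample_t"
        stat, p = stats.ttest_ind(values[0], values[1], equal_var=True)
    else:
        test = "one_way_anova"
        stat, p = stats.f_oneway(*values)
    if np.isnan(stat):  # all values identical across groups
        stat, p = 0.0, 1.0
    n_total = sum(len(v) for v in values)
    return GroupComparison(
        grouping=grouping,
        levels=[lab for lab, _ in groups],
        n=[len(v) for v in values],
        percent=[100.0 * len(v) / n_total for v in values],
        means=[float(np.mean(v)) for v in values],
        sds=[float(np.std(v, ddof=1)) if len(v) > 1 else float("nan") for v in values],
        statistic=float(stat),
        p_value=float(p),
        test=test,
    )


def correlations(panel: CohortPanel, scope: str = "pooled") -> CorrelationMatrix:
    """Pairwise Pearson r and two-sided p among the four analysis scales.

    ``scope`` is ``"pooled"`` (all visits, the default for a longitudinal
    panel) or ``"baseline"`` (visit 0 only).  Complete pairs are used per
    cell.  No multiple-testing correction is applied.
    """
    if scope not in ("pooled", "baseline"):
        raise AnalysisError(f"scope must be 'pooled' or 'baseline', got {scope!r}")
    df = panel.baseline() if scope == "baseline" else panel.df
    if len(df.dropna(subset=list(SCORE_COLUMNS))) < 3:
        raise AnalysisError("need at least 3 complete rows for correlations")

    k = len(SCORE_COLUMNS)
    r = np.eye(k)
    p = np.zeros((k, k))
    undefined: list[tuple[str, str]] = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = SCORE_COLUMNS[i], SCORE_COLUMNS[j]
            pair = df[[a, b]].dropna()
            va, vb = pair[a].to_numpy(float), pair[b].to_numpy(float)
            if len(pair) < 3 or np.std(va) == 0 or np.std(vb) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                undefined.append((a, b))
                continue
            rij, pij = stats.pearsonr(va, vb)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return CorrelationMatrix(
        variables=SCORE_COLUMNS,
        r=r,
        p=p,
        undefined=undefined,
        scope=scope,
        n=len(df),
    )
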