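"""Descriptive cohort statistics: filter accounting, Pearson chi-square
genotype comparisons and two-group Student t-tests."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterStage",
    "FilterReport",
    "filter_cohort",
    "genotype_table",
    "pearson_chi2",
    "two_group_t",
    "summary_table",
]


@dataclass(frozen=True)
class FilterStage:
    name: str
    n_entering: int
    n_removed: int
    reason: str

    @property
    def n_retained(self) -> int:
        return self.n_entering - self.n_removed


@dataclass(frozen=True)
class FilterReport:
    stages: tuple[FilterStage, ...]

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if nxt.n_entering != prev.n_retained:
                raise ValueError("filter stages are not contiguous")

    @property
    def n_initial(self) -> int:
        return self.stages[0].n_entering if self.stages else 0

    @property
    def n_final(self) -> int:
        return self.stages[-1].n_retained if self.stages else 0

    @property
    def n_removed(self) -> int:
        return sum(s.n_removed for s in self.stages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "n_entering": s.n_entering,
                    "n_removed": s.n_removed,
                    "n_retained": s.n_retained,
                    "reason": s.reason,
                }
                for s in self.stages
            ]
        )


def filter_cohort(records: pd.DataFrame) -> tuple[FilterReport, pd.DataFrame]:
    """Apply the enrolment filter chain: drop subjects without a usable MRI,
    then subjects without a TMEM106B genotype, accounting for each stage."""
    for flag in ("has_mri", "has_genotype"):
        if flag not in records.columns:
            raise ValueError(f"records are missing required flag column {flag!r}")
    n0 = len(records)
    with_mri = records.loc[records["has_mri"].astype(bool)]
    n1 = len(with_mri)
    retained = with_mri.loc[with_mri["has_genotype"].astype(bool)].reset_index(drop=True)
    n2 = len(retained)
    report = FilterReport(
        (
            FilterStage("mri", n0, n0 - n1, "no usable volumetric MRI scan"),
            FilterStage("genotype", n1, n1 - n2, "TMEM106B genotype unavailable"),
        )
    )
    return report, retained


def genotype_table(cohort: pd.DataFrame, by: str = "gs") -> pd.DataFrame:
    """Genotype (CC/CT/TT) counts cross-tabulated by a grouping column."""
    table = pd.crosstab(cohort[by], cohort["tmem"])
    return table.reindex(columns=["CC", "CT", "TT"], fill_value=0)


class Chi2Result(NamedTuple):
    statistic: float
    df: int
    p: float


def pearson_chi2(table) -> Chi2Result:
    """Plain Pearson chi-square test of independence (no continuity correction).

    *table* is an r x c count table (array or DataFrame), r, c >= 2. A zero
    row or column margin makes an expected count zero and is rejected.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("contingency table needs non-negative counts and a positive total")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero row/column margin: expected count of zero")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return Chi2Result(float(stat), int(df), float(p))


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def two_group_t(values_a, values_b) -> TTestResult:
    """Two-sided pooled-variance Student t-test."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0)
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), df, float(p))


def summary_table(cohort: pd.DataFrame, group: str = "gs") -> pd.DataFrame:
    """Per-variable descriptive comparison between the two *group* levels.

    Continuous variables (age, education) are shown as mean +/- sd with the
    Student t-test p-value; sex and each genotype as % (n); the genotype
    distribution gets one Pearson chi-square p-value.
    """
    levels = sorted(cohort[group].unique())
    if len(levels) != 2:
        raise ValueError(f"summary_table expects exactly 2 {group!r} levels, got {levels}")
    g0 = cohort.loc[cohort[group] == levels[0]]
    g1 = cohort.loc[cohort[group] == levels[1]]
    rows = []

    def fmt_mean(s: pd.Series) -> str:
        return f"{s.mean():.1f} ± {s.std(ddof=1):.1f}"

    for var in ("age", "education"):
        res = two_group_t(g0[var], g1[var])
        rows.append(
            {"variable": var, f"{group}={levels[0]}": fmt_mean(g0[var]),
             f"{group}={levels[1]}": fmt_mean(g1[var]), "test": "t", "p": res.p}
        )

    def fmt_pct(s: pd.Series, value) -> str:
        n = int((s == value).sum())
        return f"{100.0 * n / len(s):.1f} ({n})"

    sex_tab = pd.crosstab(cohort[group], cohort["female"])
    sex_p = pearson_chi2(sex_tab).p if sex_tab.shape[1] == 2 else np.nan
    rows.append(
        {"variable": "female", f"{group}={levels[0]}": fmt_pct(g0["female"], 1),
         f"{group}={levels[1]}": fmt_pct(g1["female"], 1), "test": "chi2", "p": sex_p}
    )
    geno = genotype_table(cohort, by=group)
    geno_p = pearson_chi2(geno).p
    for gt in ("CC", "CT", "TT"):
        rows.append(
            {"variable": f"TMEM106B {gt}", f"{group}={levels[0]}": fmt_pct(g0["tmem"], gt),
             f"{group}={levels[1]}": fmt_pct(g1["tmem"], gt), "test": "chi2", "p": geno_p}
        )
    return pd.DataFrame(rows)
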