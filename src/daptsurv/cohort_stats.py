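"""Grouped descriptive statistics: count (%) / mean (SD) tables comparing the
event and non-event groups, with chi-square tests for categorical covariates
and Kruskal-Wallis tests for continuous ones.

Conventions follow the usual clinical baseline table: percentages and means
rounded half-away-from-zero to one decimal; 2x2 chi-square with Yates
continuity correction (multi-category tables use the uncorrected Pearson
statistic); two-sided p <= 0.05 flagged significant; no multiple-testing
adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

ALPHA = 0.05


def pct(count: int, total: int) -> float:
    """100*count/total rounded half-away-from-zero to one decimal."""
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    if not (0 <= count <= total):
        raise ValueError(f"count {count} outside [0, {total}]")
    x = 100.0 * count / total
    return math.floor(x * 10 + 0.5) / 10.0


def _round1(x: float) -> float:
    return math.copysign(math.floor(abs(x) * 10 + 0.5) / 10.0, x)


def chisq_2x2(a: int, b: int, c: int, d: int,
              correction: bool = True) -> tuple[float, float]:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]], with Yates
    continuity correction by default."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("negative cell count")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def chisq_rxc(table: np.ndarray) -> tuple[float, float]:
    """Uncorrected Pearson chi-square for an R x C contingency table."""
    res = stats.chi2_contingency(np.asarray(table, dtype=float), correction=False)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Rank-based H statistic with tie correction, chi-square reference; all
    values identical across groups returns (0, 1) by convention."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CharacteristicRow:
    """One Table-1 row: a feature (or feature level) with per-group summaries."""

    feature: str
    kind: str                    # "categorical" | "numeric"
    level: str | None
    group_counts: dict[str, int] | None       # categorical: count per group
    group_pct: dict[str, float] | None
    group_mean_sd: dict[str, tuple[float, float]] | None  # numeric
    p_value: float | None
    test: str | None
    significant: bool | None


@dataclass
class DescriptiveTable:
    rows: list[CharacteristicRow] = field(default_factory=list)
    group_sizes: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {"characteristic": r.feature, "level": r.level or "",
                   "test": r.test or "", "p_value": r.p_value,
                   "significant": r.significant}
            for g in self.group_sizes:
                if r.kind == "categorical":
                    rec[f"{g}_count"] = r.group_counts[g]
                    rec[f"{g}_pct"] = r.group_pct[g]
                else:
                    mean, sd = r.group_mean_sd[g]
                    rec[f"{g}_mean"] = mean
                    rec[f"{g}_sd"] = sd
            recs.append(rec)
        return pd.DataFrame(recs)

    def render(self) -> str:
        """Aligned-text Table-1 rendering."""
        lines = []
        groups = list(self.group_sizes)
        header = f"{'Characteristic':<38}" + "".join(
            f"{g + f' (n={self.group_sizes[g]})':>26}" for g in groups
        ) + f"{'p':>10}"
        lines.append(header)
        lines.append("-" * len(header))
        for r in self.rows:
            label = r.feature if r.level is None else f"{r.feature} = {r.level}"
            cells = []
            for g in groups:
                if r.kind == "categorical":
                    cells.append(f"{r.group_counts[g]:,} ({r.group_pct[g]:.1f})")
                else:
                    mean, sd = r.group_mean_sd[g]
                    cells.append(f"{mean:.1f} ({sd:.1f})")
            p_str = "" if r.p_value is None else (
                "<0.0001" if r.p_value < 1e-4 else f"{r.p_value:.2g}"
            )
            star = "*" if r.significant else ""
            lines.append(f"{label:<38}" + "".join(f"{c:>26}" for c in cells)
                         + f"{p_str + star:>10}")
        return "\n".join(lines)


def describe_cohort(cohort: Cohort, group_label: np.ndarray | None = None,
                    group_names: tuple[str, str] = ("event", "no_event")) -> DescriptiveTable:
    """Event-vs-no-event baseline characteristics table.

    ``group_label`` defaults to the cohort's event indicator.  Binary and
    categorical features are summarized as count (%) per group with a
    chi-square p-value (Yates-corrected for 2x2); numerics as mean (SD) with
    Kruskal-Wallis.  Features constant across the whole cohort are reported
    with the p-value omitted.
    """
    g = cohort.events if group_label is None else np.asarray(group_label, dtype=int)
    if set(np.unique(g)) - {0, 1}:
        raise ValueError("group_label must be binary 0/1")
    in_a = g == 1
    if not in_a.any() or in_a.all():
        raise ValueError("both groups must be non-empty")
    names = {1: group_names[0], 0: group_names[1]}
    table = DescriptiveTable(group_sizes={
        names[1]: int(in_a.sum()), names[0]: int((~in_a).sum())
    })
    frame = cohort.frame
    for feat in cohort.schema.categorical:
        col = frame[feat].astype(str)
        levels = sorted(col.unique())
        counts = {lv: {names[1]: int(((col == lv) & in_a).sum()),
                       names[0]: int(((col == lv) & ~in_a).sum())}
                  for lv in levels}
        if len(levels) < 2:
            p, test, sig = None, None, None
        elif len(levels) == 2:
            lv = levels[-1]  # report the "present" level for binary flags
            a = counts[lv][names[1]]
            b = counts[lv][names[0]]
            c = table.group_sizes[names[1]] - a
            d = table.group_sizes[names[0]] - b
            _, p = chisq_2x2(a, b, c, d)
            test, sig = "chi-square (Yates)", p <= ALPHA
        else:
            mat = np.array([[counts[lv][names[1]], counts[lv][names[0]]]
                            for lv in levels])
            _, p = chisq_rxc(mat)
            test, sig = "chi-square", p <= ALPHA
        report_levels = levels[-1:] if len(levels) <= 2 else levels
        for lv in report_levels:
            table.rows.append(CharacteristicRow(
                feature=feat, kind="categorical", level=lv,
                group_counts={gn: counts[lv][gn] for gn in table.group_sizes},
                group_pct={gn: pct(counts[lv][gn], table.group_sizes[gn])
                           for gn in table.group_sizes},
                group_mean_sd=None, p_value=p, test=test, significant=sig,
            ))
    for feat in cohort.schema.numeric:
        vals = frame[feat].to_numpy(dtype=float)
        va, vb = vals[in_a], vals[~in_a]
        if np.all(vals == vals[0]):
            p, test, sig = None, None, None
        else:
            _, p = kruskal_wallis(va, vb)
            test, sig = "kruskal-wallis", p <= ALPHA
        table.rows.append(CharacteristicRow(
            feature=feat, kind="numeric", level=None, group_counts=None,
            group_pct=None,
            group_mean_sd={
                names[1]: (_round1(float(np.mean(va))),
                           _round1(float(np.std(va, ddof=1))) if len(va) > 1 else 0.0),
                names[0]: (_round1(float(np.mean(vb))),
                           _round1(float(np.std(vb, ddof=1))) if len(vb) > 1 else 0.0),
            },
            p_value=p, test=test, significant=sig,
        ))
    return table
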