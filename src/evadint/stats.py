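"""Group comparisons: one-way ANOVA, Tukey HSD post hoc, descriptive summaries.

Composite totals are treated as continuous responses.  The ANOVA is the
definitional fixed-effects decomposition

    F = (SS_between / (k - 1)) / (SS_within / (N - k)),

and pairwise comparisons use the Tukey-Kramer studentized-range statistic

    q_ij = |m_i - m_j| / sqrt(MSW / 2 * (1/n_i + 1/n_j)),

with adjusted p-values from the studentized-range distribution on
(k, N - k).  All-tied groups (e.g. a uniformly lethal arm scoring the death
override everywhere) are legal inputs and trigger a warning, not an error,
as long as the pooled within-group variance is positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import CohortScores

__all__ = [
    "AnovaResult",
    "TukeyTable",
    "DegenerateDataError",
    "anova_oneway",
    "tukey_hsd",
    "summarize",
]


class DegenerateDataError(ValueError):
    """Raised when the requested statistic is undefined for the data."""


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: Mapping[str, float]
    grand_mean: float
    ss_between: float
    ss_within: float

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


@dataclass(frozen=True)
class TukeyTable:
    """All k(k-1)/2 pairwise comparisons following a one-way ANOVA."""

    rows: tuple[tuple[str, str, float, float, float], ...]  # (i, j, mean_diff, q, p_adj)
    k: int
    df_within: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows),
            columns=["group_a", "group_b", "mean_diff", "q", "p_adj"],
        )

    def pair(self, a: str, b: str) -> tuple[float, float, float]:
        for ga, gb, diff, q, p in self.rows:
            if {ga, gb} == {a, b}:
                return diff, q, p
        raise KeyError(f"no comparison for pair ({a!r}, {b!r})")


def _check_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise DegenerateDataError(f"need >= 2 groups, got {len(groups)}")
    arrays: dict[str, np.ndarray] = {}
    for label, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise DegenerateDataError(f"group {label!r} has n = {arr.size} < 2")
        if not np.all(np.isfinite(arr)):
            raise DegenerateDataError(f"group {label!r} contains non-finite values")
        arrays[label] = arr
        if np.ptp(arr) == 0:
            warnings.warn(
                f"group {label!r} is all-tied at {arr[0]:g}; "
                "ANOVA assumptions are strained",
                stacklevel=3,
            )
    return arrays


def _decompose(arrays: Mapping[str, np.ndarray]):
    n_total = sum(a.size for a in arrays.values())
    grand = sum(a.sum() for a in arrays.values()) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    k = len(arrays)
    return n_total, grand, float(ss_between), float(ss_within), k


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA by direct sums-of-squares decomposition."""
    arrays = _check_groups(groups)
    n_total, grand, ss_between, ss_within, k = _decompose(arrays)
    df_between, df_within = k - 1, n_total - k
    if ss_within == 0:
        raise DegenerateDataError("pooled within-group variance is zero; F undefined")
    msb = ss_between / df_between
    msw = ss_within / df_within
    f = msb / msw
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(
        F=float(f),
        df_between=df_between,
        df_within=df_within,
        p=p,
        group_means={g: float(a.mean()) for g, a in arrays.items()},
        grand_mean=float(grand),
        ss_between=ss_between,
        ss_within=ss_within,
    )


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> TukeyTable:
    """Tukey(-Kramer) HSD over all group pairs, sharing the pooled MSW."""
    arrays = _check_groups(groups)
    n_total, _, _, ss_within, k = _decompose(arrays)
    df_within = n_total - k
    if ss_within == 0:
        raise DegenerateDataError("pooled within-group variance is zero; q undefined")
    msw = ss_within / df_within

    labels = list(arrays)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[labels[i]], arrays[labels[j]]
            diff = float(a.mean() - b.mean())
            se = math.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_within))
            rows.append((labels[i], labels[j], diff, float(q), min(max(p_adj, 0.0), 1.0)))
    return TukeyTable(rows=tuple(rows), k=k, df_within=df_within)


def summarize(cohort: CohortScores) -> pd.DataFrame:
    """Per-group descriptives: n, mean, SD, SEM, min, max, deaths.

    SD is the sample (n-1) standard deviation; both SD and SEM are reported
    so either style of error bar can be drawn.
    """
    rows = []
    for group, scores in cohort.by_group.items():
        totals = np.array([s.total for s in scores], dtype=float)
        n = totals.size
        sd = float(totals.std(ddof=1)) if n > 1 else float("nan")
        rows.append({
            "group": group,
            "n": n,
            "mean": float(totals.mean()),
            "sd": sd,
            "sem": sd / math.sqrt(n) if n > 1 else float("nan"),
            "min": float(totals.min()),
            "max": float(totals.max()),
            "deaths": int(sum(s.died for s in scores)),
        })
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sd", "sem", "min", "max", "deaths"])
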