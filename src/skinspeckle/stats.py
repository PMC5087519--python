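"""Reporting statistics: Pearson correlation, one-way ANOVA, group summaries.

Thin, validated wrappers over scipy.stats matching the reporting style of
the analysis: correlation tables between BA time spans, one-way ANOVA of
classification accuracies between storage times, and mean +/- SD tables per
storage group.  Pairwise Welch tests with Bonferroni correction stand in
for unnamed post-hoc letter groupings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "pearson",
    "one_way_anova",
    "group_summary",
    "pairwise_welch",
]


@dataclass(frozen=True)
class AnovaResult:
    f_value: float
    p_value: float
    df_between: int
    df_within: int
    group_means: tuple[float, ...]


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def one_way_anova(groups) -> AnovaResult:
    """Standard between/within variance decomposition.

    With two groups the F value equals the square of the pooled two-sample
    t statistic.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least 2 values")
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(g) for g in arrays)
    return AnovaResult(
        f_value=float(f),
        p_value=float(p),
        df_between=k - 1,
        df_within=n - k,
        group_means=tuple(float(g.mean()) for g in arrays),
    )


def group_summary(values_by_group: dict) -> pd.DataFrame:
    """Per-group mean and sample SD (n-1).

    Single-value groups get SD 0 with ``sd_defined=False`` flagged.
    """
    if not values_by_group:
        raise ValueError("no groups given")
    rows = []
    for name, values in values_by_group.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        rows.append(
            {
                "group": name,
                "n": int(v.size),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "sd_defined": bool(v.size > 1),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def pairwise_welch(values_by_group: dict) -> pd.DataFrame:
    """All pairwise Welch t-tests with Bonferroni-corrected p values."""
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("pairwise comparison needs at least 2 groups")
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            t, p = sps.ttest_ind(
                np.asarray(values_by_group[a], dtype=float),
                np.asarray(values_by_group[b], dtype=float),
                equal_var=False,
            )
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "t": float(t),
                    "p": float(p),
                    "p_bonferroni": float(min(p * m, 1.0)),
                }
            )
    return pd.DataFrame(rows)
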