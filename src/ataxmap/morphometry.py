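"""Group summaries and one-way ANOVA for paranodal-length measurements."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputDataError

GROUPS = ("control_wt", "affected_in_lesion", "affected_out_lesion")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    se: float | None  # None when n == 1
    minimum: float
    maximum: float


def _validate(measures: pd.DataFrame) -> pd.DataFrame:
    required = {"length_um", "group"}
    if not required <= set(measures.columns):
        raise InputDataError(f"measurement table must have columns {sorted(required)}")
    lengths = measures["length_um"].to_numpy(dtype=float)
    if not np.isfinite(lengths).all() or (lengths <= 0).any():
        raise InputDataError("lengths must be positive and finite")
    return measures


def summarize_groups(measures: pd.DataFrame) -> list[GroupSummary]:
    """Per-group n, mean, standard error and range.

    The SE of a single measurement is undefined and reported as None.
    """
    if measures.empty:
        return []
    _validate(measures)
    out: list[GroupSummary] = []
    for group, sub in measures.groupby("group", sort=False):
        x = sub["length_um"].to_numpy(dtype=float)
        se = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else None
        out.append(
            GroupSummary(
                group=str(group),
                n=int(x.size),
                mean=float(x.mean()),
                se=se,
                minimum=float(x.min()),
                maximum=float(x.max()),
            )
        )
    return out


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float
    ss_total: float


def anova_oneway(measures: pd.DataFrame, *, log_scale: bool = False) -> AnovaResult:
    """Classical one-way between/within variance decomposition.

    ``log_scale`` analyses log lengths (off by default: raw lengths are
    the published analysis scale even though they are right-skewed).
    """
    _validate(measures)
    groups = [
        sub["length_um"].to_numpy(dtype=float) for _, sub in measures.groupby("group", sort=False)
    ]
    if len(groups) < 2:
        raise InputDataError("anova_oneway requires at least two groups")
    if log_scale:
        groups = [np.log(g) for g in groups]
    n_total = sum(g.size for g in groups)
    k = len(groups)
    if n_total <= k:
        raise InputDataError("anova_oneway requires total n greater than the number of groups")
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        warnings.warn("zero within-group variance; F is infinite", stacklevel=2)
        return AnovaResult(np.inf, df_b, df_w, 0.0, ss_between, 0.0, ss_between)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(f, df_b, df_w, p, ss_between, ss_within, ss_between + ss_within)


def tukey_pairwise(measures: pd.DataFrame) -> pd.DataFrame:
    """Optional Tukey HSD post-hoc comparisons (not applied by default)."""
    _validate(measures)
    named = {str(g): sub["length_um"].to_numpy(dtype=float)
             for g, sub in measures.groupby("group", sort=False)}
    res = stats.tukey_hsd(*named.values())
    names = list(named)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(named[names[i]].mean() - named[names[j]].mean()),
                    "p_value": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)
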