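"""Group summaries (mean +- SEM) and the comparison-test selection rule.

Two groups are compared with Student's t-test, or with the Mann-Whitney U
test when heterogeneity of variance is detected; three or more groups with
one-way ANOVA plus post-hoc Tukey, or with the rank-based one-way ANOVA
(Kruskal-Wallis) under heterogeneity.  Heterogeneity of variance is
operationalized as Levene's test (median-centered, i.e. Brown-Forsythe) at
alpha = 0.05.  p < 0.05 is considered significant throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError


@dataclass
class GroupSummary:
    """Mean +- SEM of one experimental group."""

    group_tag: str
    n: int
    mean: float
    sem: float
    values: np.ndarray


@dataclass
class ComparisonResult:
    groups: list[str]
    method_used: str  # {t_test, anova_tukey, mann_whitney, nonparametric_anova}
    statistic: float
    p_value: float
    variance_heterogeneity_detected: bool
    significant: bool
    posthoc: pd.DataFrame | None = None


def _validated(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for tag, vals in groups.items():
        arr = np.asarray(vals, dtype=float).ravel()
        if arr.size < 2:
            raise ValidationError(f"group {tag!r} needs n >= 2 (got {arr.size})")
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"group {tag!r} contains non-finite values")
        out[tag] = arr
    return out


def summarize(groups: dict[str, np.ndarray]) -> list[GroupSummary]:
    """Mean and SEM (sample SD / sqrt(n)) per group."""
    groups = _validated(groups)
    return [
        GroupSummary(
            group_tag=tag,
            n=v.size,
            mean=float(v.mean()),
            sem=float(v.std(ddof=1) / np.sqrt(v.size)),
            values=v,
        )
        for tag, v in groups.items()
    ]


def compare(groups: dict[str, np.ndarray], alpha: float = 0.05) -> ComparisonResult:
    """Compare 2+ groups with the parametric/nonparametric selection rule."""
    groups = _validated(groups)
    if len(groups) < 2:
        raise ValidationError("compare needs at least two groups")
    tags = list(groups)
    samples = [groups[t] for t in tags]

    lev_stat, lev_p = sps.levene(*samples, center="median")
    heterogeneous = bool(np.isfinite(lev_p) and lev_p < alpha)

    posthoc = None
    if len(samples) == 2:
        if heterogeneous:
            res = sps.mannwhitneyu(*samples, alternative="two-sided")
            method = "mann_whitney"
        else:
            res = sps.ttest_ind(*samples, equal_var=True)
            method = "t_test"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if heterogeneous:
            res = sps.kruskal(*samples)
            method = "nonparametric_anova"
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            res = sps.f_oneway(*samples)
            method = "anova_tukey"
            stat, p = float(res.statistic), float(res.pvalue)
            tk = sps.tukey_hsd(*samples)
            rows = []
            for i in range(len(samples)):
                for j in range(i + 1, len(samples)):
                    rows.append(
                        {
                            "group_a": tags[i],
                            "group_b": tags[j],
                            "mean_diff": float(samples[i].mean() - samples[j].mean()),
                            "p_value": float(tk.pvalue[i, j]),
                        }
                    )
            posthoc = pd.DataFrame(rows)

    if np.isnan(p):  # zero-variance degenerate input: no evidence of difference
        p = 1.0
    return ComparisonResult(
        groups=tags,
        method_used=method,
        statistic=stat,
        p_value=p,
        variance_heterogeneity_detected=heterogeneous,
        significant=p < alpha,
        posthoc=posthoc,
    )
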