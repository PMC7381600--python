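"""Group-level comparison of volume metrics.

Muscle types are compared with one-way ANOVA followed by Tukey's HSD
post-hoc test at family-wise alpha, with the muscle volume as the unit
of analysis (group means are reported as mean +/- SE over volumes).
Tukey adjusted p-values use the studentized-range distribution with the
Tukey-Kramer allowance for unequal group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "group_compare"]


@dataclass
class GroupComparison:
    """One-way ANOVA + Tukey HSD over per-volume metric values."""

    groups: list[str]
    values: dict[str, np.ndarray]
    means: dict[str, float]
    sems: dict[str, float]
    f_stat: float
    p_value: float
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj, significant
    alpha: float

    def pairwise_p(self, g1: str, g2: str) -> float:
        t = self.tukey
        row = t[((t.group1 == g1) & (t.group2 == g2)) | ((t.group1 == g2) & (t.group2 == g1))]
        if row.empty:
            raise KeyError(f"no pair ({g1}, {g2})")
        return float(row.p_adj.iloc[0])

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [
            (r.group1, r.group2)
            for r in self.tukey.itertuples()
            if r.significant
        ]


def group_compare(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """Compare a metric across muscle groups (ANOVA + Tukey HSD).

    Requires at least two groups with at least two volumes each and
    nonzero pooled within-group variance; degenerate inputs raise
    explicit errors rather than propagating NaN.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("group comparison requires at least two groups")
    arrays = {g: np.asarray(values_by_group[g], dtype=float) for g in groups}
    for g, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than two volumes; cannot infer")
        if np.any(~np.isfinite(a)):
            raise ValueError(f"group {g!r} contains non-finite values")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")

    n_total = sum(a.size for a in arrays.values())
    k = len(groups)
    df_within = n_total - k
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    if ss_within == 0:
        raise ValueError("zero within-group variance; F statistic undefined")

    f_stat, p_value = sps.f_oneway(*arrays.values())
    ms_within = ss_within / df_within

    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            a, b = arrays[g1], arrays[g2]
            diff = b.mean() - a.mean()
            se = np.sqrt(ms_within / 2.0 * (1.0 / a.size + 1.0 / b.size))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_within))
            p_adj = min(1.0, max(0.0, p_adj))
            rows.append((g1, g2, diff, p_adj, p_adj < alpha))
    tukey = pd.DataFrame(
        rows, columns=["group1", "group2", "mean_diff", "p_adj", "significant"]
    )

    return GroupComparison(
        groups=groups,
        values=arrays,
        means={g: float(a.mean()) for g, a in arrays.items()},
        sems={g: float(a.std(ddof=1) / np.sqrt(a.size)) for g, a in arrays.items()},
        f_stat=float(f_stat),
        p_value=float(p_value),
        tukey=tukey,
        alpha=alpha,
    )
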