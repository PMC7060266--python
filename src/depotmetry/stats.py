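"""Group comparisons: one-way ANOVA with Tukey HSD post-hoc tests.

Substance groups (e.g. half-lifes or sphericities per filler) are compared
with a classical one-way ANOVA; pairwise differences are then assessed
with Tukey's honestly significant difference test on the studentized-range
distribution, which corrects for the all-pairs multiplicity.  Unequal
group sizes use the Tukey–Kramer harmonic-mean adjustment.  Significance
is declared at α = 0.05 (configurable).  Homogeneity of variances is the
caller's concern, as is any correction across different *parameters*
(volume, sphericity, half-life are each tested on their own).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["AnovaTukeyResult", "anova_tukey"]


@dataclass(frozen=True)
class AnovaTukeyResult:
    """One-way ANOVA F/p plus Tukey HSD pairwise comparisons."""

    f_statistic: float
    p_anova: float
    group_stats: pd.DataFrame  # index group; columns n, mean, sd
    pairwise: pd.DataFrame  # columns group1, group2, mean_diff, p_tukey, significant
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_anova < self.alpha

    def summary(self) -> str:
        lines = [
            "One-way ANOVA + Tukey HSD",
            "=" * 60,
            f"F = {self.f_statistic:.4f}, p = {self.p_anova:.4g} "
            f"({'significant' if self.significant else 'not significant'} at alpha={self.alpha})",
            "",
            self.group_stats.to_string(),
            "",
            self.pairwise.to_string(index=False),
        ]
        return "\n".join(lines)


def anova_tukey(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> AnovaTukeyResult:
    """Compare ≥2 groups of measurements.

    Degenerate input where every value in every group is identical is
    well-defined: F = 0 and all p-values are 1 (no evidence of any
    difference), rather than the 0/0 a naive computation would produce.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        a = np.asarray(list(vals), dtype=float)
        a = a[np.isfinite(a)]
        if a.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 finite values")
        arrays[name] = a
    names = list(arrays)

    stats_df = pd.DataFrame(
        {
            "n": [arrays[g].size for g in names],
            "mean": [arrays[g].mean() for g in names],
            "sd": [arrays[g].std(ddof=1) for g in names],
        },
        index=pd.Index(names, name="group"),
    )

    all_vals = np.concatenate([arrays[g] for g in names])
    degenerate = np.ptp(all_vals) == 0
    if degenerate:
        f_stat, p_anova = 0.0, 1.0
    else:
        f_stat, p_anova = sps.f_oneway(*[arrays[g] for g in names])
        f_stat, p_anova = float(f_stat), float(p_anova)

    rows = []
    if degenerate:
        for g1, g2 in itertools.combinations(names, 2):
            rows.append({"group1": g1, "group2": g2, "mean_diff": 0.0, "p_tukey": 1.0})
    else:
        hsd = sps.tukey_hsd(*[arrays[g] for g in names])
        for i, j in itertools.combinations(range(len(names)), 2):
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": float(arrays[names[i]].mean() - arrays[names[j]].mean()),
                    "p_tukey": float(hsd.pvalue[i, j]),
                }
            )
    pairwise = pd.DataFrame(rows)
    pairwise["significant"] = pairwise["p_tukey"] < alpha
    return AnovaTukeyResult(
        f_statistic=f_stat,
        p_anova=p_anova,
        group_stats=stats_df,
        pairwise=pairwise,
        alpha=alpha,
    )
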