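"""One-way ANOVA and Tukey's honest significant difference test.

Replicate-level metrics (e.g. Fe(II) production rates of the four species
under one growth condition) are compared with a classical one-way ANOVA
followed by all-pairs Tukey HSD using the studentized range distribution;
unequal group sizes use the Tukey-Kramer standard error.  Significance
stars follow the figure-annotation convention *** p < 0.001, ** p < 0.01
(and * p < alpha for completeness).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["one_way_anova", "tukey_hsd", "GroupComparison", "PairwiseRow", "stars_for_p"]


def stars_for_p(p: float, alpha: float = 0.05) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return ""


def _validated(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out: dict[str, np.ndarray] = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} needs at least 2 values")
        out[str(label)] = arr
    pooled = np.concatenate(list(out.values()))
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical; variance is degenerate")
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA; returns (F, p).

    Computed from between/within sums of squares; the residual mean square is
    shared with :func:`tukey_hsd`.
    """
    data = _validated(groups)
    k = len(data)
    values = np.concatenate(list(data.values()))
    n_total = values.size
    grand = values.mean()
    ss_between = sum(arr.size * (arr.mean() - grand) ** 2 for arr in data.values())
    ss_within = sum(float(np.sum((arr - arr.mean()) ** 2)) for arr in data.values())
    df_between = k - 1
    df_within = n_total - k
    if df_within <= 0:
        raise ValueError("no residual degrees of freedom")
    if ss_within == 0:
        raise ValueError("zero within-group variance; F is degenerate")
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p


@dataclasses.dataclass(frozen=True)
class PairwiseRow:
    group_a: str
    group_b: str
    mean_difference: float
    q_statistic: float
    p_adjusted: float
    stars: str


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    labels: tuple[str, ...]
    group_n: tuple[int, ...]
    f_statistic: float
    anova_p: float
    alpha: float
    pairwise: tuple[PairwiseRow, ...]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "group_a": r.group_a,
                    "group_b": r.group_b,
                    "mean_difference": r.mean_difference,
                    "q_statistic": r.q_statistic,
                    "p_adjusted": r.p_adjusted,
                    "stars": r.stars,
                }
                for r in self.pairwise
            ]
        )


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> GroupComparison:
    """All-pairs Tukey HSD with studentized-range adjusted p-values.

    For groups i, j with means m_i, m_j and pooled residual mean square MSE
    on N - k degrees of freedom,

        q_ij = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j))

    and the adjusted p is the studentized-range survival function at q_ij
    with k groups and N - k df (Tukey-Kramer for unequal n).  ``alpha`` only
    affects the star annotation, never the statistics.
    """
    data = _validated(groups)
    f_stat, anova_p = one_way_anova(groups)
    k = len(data)
    n_total = sum(arr.size for arr in data.values())
    df = n_total - k
    mse = sum(float(np.sum((arr - arr.mean()) ** 2)) for arr in data.values()) / df

    rows = []
    for a, b in itertools.combinations(data, 2):
        xa, xb = data[a], data[b]
        diff = float(xa.mean() - xb.mean())
        se = np.sqrt(mse / 2.0 * (1.0 / xa.size + 1.0 / xb.size))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df))
        p = min(max(p, 0.0), 1.0)
        rows.append(
            PairwiseRow(
                group_a=a,
                group_b=b,
                mean_difference=diff,
                q_statistic=float(q),
                p_adjusted=p,
                stars=stars_for_p(p, alpha),
            )
        )
    return GroupComparison(
        labels=tuple(data),
        group_n=tuple(arr.size for arr in data.values()),
        f_statistic=f_stat,
        anova_p=anova_p,
        alpha=alpha,
        pairwise=tuple(rows),
    )
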