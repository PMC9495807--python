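"""One-way ANOVA and Tukey HSD on per-station total abundance.

The model compares mean total copepod abundance across the water-mass
groups via the classical between/within sum-of-squares decomposition, then
runs all pairwise Tukey comparisons.  Groups are unbalanced, so the
Tukey-Kramer form of the studentized-range statistic is used,

.. math:: q_{jk} = \\frac{|\\bar y_j - \\bar y_k|}
                        {\\sqrt{MS_W (1/n_j + 1/n_k) / 2}},

with the adjusted p-value taken from the studentized-range distribution
with (number of groups, within-group df); scipy evaluates that CDF by
direct numerical quadrature (absolute tolerance well below 1e-4).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceMatrix, GroupPartition
from .errors import ValidationError


def station_totals(abund: AbundanceMatrix) -> pd.Series:
    """Total abundance per station (row sums, ind m^-3)."""
    return pd.Series(
        abund.values.sum(axis=1), index=abund.station_ids, name="total_abundance"
    )


@dataclasses.dataclass(frozen=True)
class AnovaResults:
    """One-way ANOVA decomposition plus Tukey-Kramer pairwise table."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float
    ms_within: float
    group_stats: pd.DataFrame  # index group; n, mean, sd
    tukey: pd.DataFrame  # group_1, group_2, diff, q, p_adj, zero_variance

    def summary(self) -> str:
        lines = [
            "One-way ANOVA on station totals",
            f"  F({self.df_between}, {self.df_within}) = "
            f"{self.f_statistic:.4f}, p = {self.p_value:.4g}",
            "",
            self.group_stats.to_string(float_format=lambda v: f"{v:.2f}"),
            "",
            "Tukey-Kramer pairwise comparisons",
            self.tukey.to_string(index=False,
                                 float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class AbundanceAnova:
    """One-way fixed-effects model of a per-station quantity on the group
    partition."""

    def __init__(self, values: pd.Series, partition: GroupPartition):
        aligned = values.reindex(partition.station_ids)
        if aligned.isna().any():
            missing = list(aligned.index[aligned.isna()])
            raise ValidationError(f"stations without values: {missing}")
        sizes = partition.group_sizes
        if len(sizes) < 2:
            raise ValidationError("ANOVA needs at least 2 groups")
        small = sizes[sizes < 2]
        if len(small):
            raise ValidationError(
                f"every group needs >= 2 stations; too small: "
                f"{dict(small)}"
            )
        self.values = aligned.astype(float)
        self.partition = partition

    def fit(self) -> AnovaResults:
        y = self.values
        groups = self.partition.labels.reindex(y.index)
        labels = self.partition.group_labels
        k = len(labels)
        n = len(y)
        grand = y.mean()

        stats_rows = {}
        ssb = 0.0
        ssw = 0.0
        for g in labels:
            yg = y[groups == g]
            ssb += len(yg) * (yg.mean() - grand) ** 2
            ssw += float(((yg - yg.mean()) ** 2).sum())
            stats_rows[g] = {
                "n": len(yg), "mean": yg.mean(), "sd": yg.std(ddof=1)
            }
        group_stats = pd.DataFrame.from_dict(stats_rows, orient="index")
        group_stats.index.name = "group"

        dfb, dfw = k - 1, n - k
        msw = ssw / dfw
        if msw == 0.0:
            f = 0.0 if ssb == 0.0 else np.inf
        else:
            f = (ssb / dfb) / msw
        p = 1.0 if f == 0.0 else float(stats.f.sf(f, dfb, dfw))

        rows = []
        for g1, g2 in itertools.combinations(labels, 2):
            m1, m2 = group_stats.at[g1, "mean"], group_stats.at[g2, "mean"]
            n1, n2 = group_stats.at[g1, "n"], group_stats.at[g2, "n"]
            diff = m2 - m1
            se = np.sqrt(msw * (1.0 / n1 + 1.0 / n2) / 2.0)
            zero_var = msw == 0.0
            if zero_var:
                q = 0.0 if diff == 0.0 else np.inf
                p_adj = 1.0 if diff == 0.0 else 0.0
            else:
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, dfw))
            rows.append(
                {"group_1": g1, "group_2": g2, "diff": diff, "q": q,
                 "p_adj": min(max(p_adj, 0.0), 1.0), "zero_variance": zero_var}
            )
        tukey = pd.DataFrame(rows)
        return AnovaResults(
            f_statistic=float(f), df_between=dfb, df_within=dfw,
            p_value=min(max(p, 0.0), 1.0), ss_between=float(ssb),
            ss_within=float(ssw), ms_within=float(msw),
            group_stats=group_stats, tukey=tukey,
        )


def oneway_anova(values: pd.Series, partition: GroupPartition) -> AnovaResults:
    """Functional wrapper around :class:`AbundanceAnova`."""
    return AbundanceAnova(values, partition).fit()


def tukey_hsd(values: pd.Series, partition: GroupPartition) -> pd.DataFrame:
    """Tukey-Kramer pairwise table (see :class:`AbundanceAnova`)."""
    return AbundanceAnova(values, partition).fit().tukey
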