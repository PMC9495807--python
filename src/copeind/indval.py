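"""Indicator-value (IndVal) analysis in the Dufrene-Legendre sense.

For taxon *i* and station group *j*:

* specificity ``A_ij = Nindividuals_ij / Nindividuals_i``, where
  ``Nindividuals_ij`` is the arithmetic mean abundance of *i* over *all*
  sites of group *j* (zero-abundance sites included) and
  ``Nindividuals_i`` sums those group means over groups;
* fidelity ``B_ij = Nsite_ij / Nsite_j``, the fraction of group-*j* sites
  where the taxon is present (abundance strictly > 0);
* ``IndVal_ij = 100 * A_ij * B_ij``.

A taxon is an indicator of the group where its IndVal exceeds the
selection threshold (strictly greater than, default 50%).  Permutation
inference shuffles station group labels and compares each observed value
against the permuted distribution of the taxon's *maximum* group IndVal.

The module also provides a consistency solver for published IndVal tables:
given printed per-group mean abundances and IndVal percentages but unknown
group sizes, it brute-forces all group-size compositions of the station
total and all integer presence counts, returning the composition that
minimises the worst absolute residual between recomputed and printed
IndVal.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, GroupPartition
from .errors import ValidationError


# ---------------------------------------------------------------------------
# core statistic


def _group_arrays(
    abund: AbundanceMatrix, partition: GroupPartition
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """(group mean abundances g x p, presence counts g x p, labels, sizes)."""
    missing = [s for s in abund.station_ids if s not in partition.labels.index]
    if missing:
        raise ValidationError(f"stations without group label: {missing}")
    extra = [s for s in partition.station_ids if s not in abund.station_ids]
    if extra:
        raise ValidationError(f"partition has unknown stations: {extra}")
    labels = partition.group_labels
    if len(labels) < 2:
        raise ValidationError("IndVal needs at least 2 groups")
    x = abund.values
    member = np.stack(
        [
            np.asarray(
                partition.labels.reindex(abund.station_ids).to_numpy() == g
            )
            for g in labels
        ]
    )  # g x n boolean
    sizes = member.sum(axis=1)
    if (sizes == 0).any():
        empty = [labels[i] for i in np.where(sizes == 0)[0]]
        raise ValidationError(f"empty group(s): {empty}")
    means = member @ x / sizes[:, None]
    presence = member @ (x > 0).astype(float)
    return means, presence, labels, sizes


def _indval_from_arrays(
    means: np.ndarray, presence: np.ndarray, sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(A, B, IndVal, summed group means) from group-level arrays."""
    totals = means.sum(axis=0)  # Nindividuals_i per taxon
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(totals > 0, means / np.where(totals > 0, totals, 1.0), 0.0)
    b = presence / sizes[:, None]
    return a, b, 100.0 * a * b, totals


def indval_table(
    abund: AbundanceMatrix, partition: GroupPartition
) -> pd.DataFrame:
    """Long-format IndVal table, one row per (taxon, group).

    Columns: ``mean_abundance`` (Nindividuals_ij), ``summed_group_means``
    (Nindividuals_i), ``n_sites_present`` (Nsite_ij), ``group_size``
    (Nsite_j), ``specificity`` (A), ``fidelity`` (B), ``indval`` (%), and
    ``absent_everywhere`` flagging taxa with no individuals anywhere
    (their IndVal is 0 in every group).
    """
    means, presence, labels, sizes = _group_arrays(abund, partition)
    a, b, iv, totals = _indval_from_arrays(means, presence, sizes)
    taxa = abund.taxon_ids
    rows = []
    for gi, g in enumerate(labels):
        for ti, t in enumerate(taxa):
            rows.append(
                {
                    "taxon": t,
                    "group": g,
                    "mean_abundance": means[gi, ti],
                    "summed_group_means": totals[ti],
                    "n_sites_present": int(presence[gi, ti]),
                    "group_size": int(sizes[gi]),
                    "specificity": a[gi, ti],
                    "fidelity": b[gi, ti],
                    "indval": iv[gi, ti],
                    "absent_everywhere": totals[ti] == 0.0,
                }
            )
    return pd.DataFrame(rows)


def select_indicators(
    table: pd.DataFrame, threshold: float = 50.0
) -> pd.DataFrame:
    """Taxa whose IndVal strictly exceeds ``threshold`` (%), grouped and
    sorted by descending IndVal within each group."""
    if not (0.0 < threshold < 100.0):
        raise ValidationError("threshold must lie in (0, 100)")
    hits = table[table["indval"] > threshold]
    return (
        hits.sort_values(["group", "indval"], ascending=[True, False],
                         kind="stable")
        .loc[:, ["group", "taxon", "indval", "specificity", "fidelity"]]
        .reset_index(drop=True)
    )


def indval_permutation_p(
    abund: AbundanceMatrix,
    partition: GroupPartition,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Permutation p-values per (taxon, group).

    Station group labels are permuted; each observed IndVal_ij is compared
    against the permuted distribution of the taxon's maximum group IndVal:
    ``p = (1 + #{permuted max >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValidationError("use at least 99 permutations")
    means, presence, labels, sizes = _group_arrays(abund, partition)
    _, _, observed, _ = _indval_from_arrays(means, presence, sizes)

    rng = np.random.default_rng(seed)
    x = abund.values
    pres = (x > 0).astype(float)
    member = np.stack(
        [
            partition.labels.reindex(abund.station_ids).to_numpy() == g
            for g in labels
        ]
    ).astype(float)
    counts = np.zeros_like(observed)
    n = x.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        m = member[:, perm]
        pm = m @ x / sizes[:, None]
        pp = m @ pres
        _, _, iv, _ = _indval_from_arrays(pm, pp, sizes)
        counts += iv.max(axis=0)[None, :] >= observed
    p = (1.0 + counts) / (1.0 + n_perm)
    taxa = abund.taxon_ids
    rows = []
    for gi, g in enumerate(labels):
        for ti, t in enumerate(taxa):
            rows.append({"taxon": t, "group": g, "indval": observed[gi, ti],
                         "p_value": p[gi, ti]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results


class IndicatorValueModel:
    """IndVal model on an abundance matrix and a station partition."""

    def __init__(self, abund: AbundanceMatrix, partition: GroupPartition):
        self.abund = abund
        self.partition = partition
        _group_arrays(abund, partition)  # validate eagerly

    def fit(
        self,
        permutations: int = 0,
        seed: int | None = None,
    ) -> "IndValResults":
        table = indval_table(self.abund, self.partition)
        pvalues = None
        if permutations:
            pvalues = indval_permutation_p(
                self.abund, self.partition, n_perm=permutations, seed=seed
            )
        return IndValResults(model=self, table=table, pvalues=pvalues)


@dataclasses.dataclass(frozen=True)
class IndValResults:
    """Fitted IndVal table with optional permutation inference."""

    model: IndicatorValueModel
    table: pd.DataFrame
    pvalues: pd.DataFrame | None

    def matrix(self, column: str = "indval") -> pd.DataFrame:
        """Taxa x groups pivot of one statistic."""
        return self.table.pivot(index="taxon", columns="group", values=column)

    def select(self, threshold: float = 50.0) -> pd.DataFrame:
        return select_indicators(self.table, threshold=threshold)

    def summary(self, threshold: float = 50.0) -> str:
        sel = self.select(threshold)
        lines = [
            "Indicator-value analysis "
            f"({self.table['taxon'].nunique()} taxa, "
            f"{self.table['group'].nunique()} groups)",
            f"indicators with IndVal > {threshold:g}%:",
        ]
        for g, sub in sel.groupby("group"):
            taxa = ", ".join(
                f"{r.taxon} ({r.indval:.2f})" for r in sub.itertuples()
            )
            lines.append(f"  group {g}: {taxa}")
        if sel.empty:
            lines.append("  (none)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# consistency solver for printed tables


@dataclasses.dataclass(frozen=True)
class GroupSizeSolution:
    """Best group-size composition reconstructed from a printed table."""

    sizes: tuple[int, ...]
    groups: tuple[str, ...]
    presence: pd.DataFrame  # taxa x groups integer counts (NaN: unprinted)
    max_residual: float
    second_best_residual: float
    ambiguous: bool
    consistent: bool


def infer_group_sizes(
    abundances: pd.DataFrame,
    indvals: pd.DataFrame,
    total_stations: int,
    min_group_size: int = 1,
    residual_budget: float = 1.0,
) -> GroupSizeSolution:
    """Brute-force the group sizes behind a printed IndVal table.

    ``abundances`` and ``indvals`` are taxa x groups frames of printed
    per-group mean abundances and IndVal percentages; NaN marks unprinted
    cells (unprinted abundances count as zero in the specificity
    denominator, matching tables that print "/" for absent taxa).

    Every composition of ``total_stations`` into the groups (each >=
    ``min_group_size``) is scored by the worst absolute residual between
    recomputed ``100 * A * c / n_j`` (over integer presence counts ``c``)
    and the printed IndVal.  The minimiser is returned; ``ambiguous`` is
    set when another composition ties it to within 1e-9, and
    ``consistent`` is False when even the best composition misses by
    ``residual_budget`` or more.
    """
    if not abundances.index.equals(indvals.index) or not (
        abundances.columns.equals(indvals.columns)
    ):
        raise ValidationError("abundance and indval frames must align")
    if len(abundances) < 1:
        raise ValidationError("need at least one printed taxon")
    groups = tuple(str(g) for g in abundances.columns)
    g = len(groups)
    ab = abundances.fillna(0.0).to_numpy(dtype=float)
    totals = ab.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(totals[:, None] > 0, ab / totals[:, None], 0.0)
    iv = indvals.to_numpy(dtype=float)
    printed = ~np.isnan(iv)

    best: tuple[float, tuple[int, ...], np.ndarray] | None = None
    second = np.inf
    for sizes in _compositions(total_stations, g, min_group_size):
        max_res = 0.0
        pres = np.full_like(iv, np.nan)
        for ti, gi in zip(*np.where(printed)):
            n_j = sizes[gi]
            candidates = 100.0 * a[ti, gi] * np.arange(n_j + 1) / n_j
            res = np.abs(candidates - iv[ti, gi])
            c = int(res.argmin())
            pres[ti, gi] = c
            max_res = max(max_res, float(res[c]))
        if best is None or max_res < best[0] - 1e-12:
            if best is not None:
                second = min(second, best[0])
            best = (max_res, sizes, pres)
        else:
            second = min(second, max_res)
    assert best is not None
    max_res, sizes, pres = best
    presence = pd.DataFrame(pres, index=abundances.index, columns=groups)
    return GroupSizeSolution(
        sizes=sizes,
        groups=groups,
        presence=presence,
        max_residual=max_res,
        second_best_residual=float(second),
        ambiguous=bool(second <= max_res + 1e-9),
        consistent=bool(max_res < residual_budget),
    )


def _compositions(total: int, parts: int, minimum: int):
    """All ordered compositions of ``total`` into ``parts`` parts, each >=
    ``minimum``."""
    if parts == 1:
        if total >= minimum:
            yield (total,)
        return
    for first in range(minimum, total - minimum * (parts - 1) + 1):
        for rest in _compositions(total - first, parts - 1, minimum):
            yield (first, *rest)
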