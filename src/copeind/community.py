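"""Dominance and taxonomic-composition statistics.

For each taxon *i* with abundance :math:`x_{s,i}` at station *s*:

* mean abundance ``MA_i`` — arithmetic mean of :math:`x_{s,i}` over stations,
* relative abundance ``RA_i`` — ``100 * MA_i / sum_i MA_i`` (so RA is the
  ratio of station-averaged abundances, not a per-station RA averaged over
  stations; the two differ whenever station totals vary),
* occurrence rate ``OR_i`` — percentage of stations where the taxon is
  present (strictly positive abundance).

Order-level composition counts species (copepodite categories excluded)
and sums mean abundance (copepodites included within their order).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, TaxonMeta, COPEPOD_ORDERS
from .errors import ValidationError


@dataclasses.dataclass(frozen=True)
class DominanceTable:
    """Per-taxon MA / RA / OR plus the total mean abundance."""

    per_taxon: pd.DataFrame  # index taxon; columns MA, RA, OR
    total_mean_abundance: float

    def __post_init__(self) -> None:
        ra_sum = float(self.per_taxon["RA"].sum())
        if abs(ra_sum - 100.0) > 1e-9:
            raise ValidationError(f"relative abundances sum to {ra_sum}, not 100")


def dominance_table(abund: AbundanceMatrix) -> DominanceTable:
    """Mean abundance, relative abundance and occurrence rate per taxon."""
    values = abund.values
    ma = values.mean(axis=0)
    total = float(ma.sum())
    if total <= 0.0:
        raise ValidationError(
            "all-zero abundance matrix: relative abundance is undefined"
        )
    ra = 100.0 * ma / total
    occ = 100.0 * (values > 0).mean(axis=0)
    table = pd.DataFrame(
        {"MA": ma, "RA": ra, "OR": occ},
        index=pd.Index(abund.taxon_ids, name="taxon"),
    )
    return DominanceTable(per_taxon=table, total_mean_abundance=total)


def order_composition(abund: AbundanceMatrix, taxa: TaxonMeta) -> pd.DataFrame:
    """Species counts and mean-abundance totals per copepod order.

    Returns a DataFrame indexed by order with columns ``n_species``,
    ``species_share`` (%), ``mean_abundance`` (ind m^-3 summed over the
    order's taxa) and ``abundance_share`` (%).  Orders absent from the
    data are omitted.
    """
    taxa.require_covers(abund)
    meta = taxa.data.loc[abund.taxon_ids]
    ma = pd.Series(abund.values.mean(axis=0), index=abund.taxon_ids)

    rows = {}
    for order in COPEPOD_ORDERS:
        in_order = meta.index[meta["order"] == order]
        if len(in_order) == 0:
            continue
        is_species = ~meta.loc[in_order, "is_copepodite"]
        rows[order] = {
            "n_species": int(is_species.sum()),
            "mean_abundance": float(ma.loc[in_order].sum()),
        }
    comp = pd.DataFrame.from_dict(rows, orient="index")
    comp.index.name = "order"
    n_species_total = comp["n_species"].sum()
    if n_species_total == 0:
        raise ValidationError("no species-level taxa: species shares undefined")
    comp["species_share"] = 100.0 * comp["n_species"] / n_species_total
    comp["abundance_share"] = (
        100.0 * comp["mean_abundance"] / comp["mean_abundance"].sum()
    )
    return comp[["n_species", "species_share", "mean_abundance", "abundance_share"]]


def dominant_taxa(
    dom: DominanceTable,
    ra_threshold: float = 2.0,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Taxa with RA >= ``ra_threshold`` (%), ranked by descending RA.

    ``top_n``, when given, overrides the threshold and returns the ``top_n``
    highest-RA taxa instead.
    """
    if not (0.0 < ra_threshold <= 100.0):
        raise ValidationError("ra_threshold must lie in (0, 100]")
    ranked = dom.per_taxon.sort_values("RA", ascending=False, kind="stable")
    if top_n is not None:
        if top_n < 1:
            raise ValidationError("top_n must be >= 1")
        return ranked.head(top_n)
    return ranked[ranked["RA"] >= ra_threshold]
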