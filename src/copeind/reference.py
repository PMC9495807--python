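"""Published reference values from the northeast-Taiwan autumn copepod
survey that this package's defaults emulate.

Shipped as plain-text package data so that validation suites and the
reproduction script can use the printed tables as inputs:

* ``indicator_reference.csv`` — per-group mean abundance (ind m^-3) and
  IndVal (%) of the 22 reported indicator-table taxa; empty cells mark
  values the source did not print.
* ``dominance_reference.csv`` — mean abundance, relative abundance and
  occurrence rate of the ten dominant taxa.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import pandas as pd

#: survey-wide total mean abundance, ind m^-3
TOTAL_MEAN_ABUNDANCE = 774.24

#: number of stations implied by all occurrence rates being multiples of 4%
TOTAL_STATIONS = 25

#: order-level composition of the emulated survey
ORDER_REFERENCE = pd.DataFrame(
    {
        "n_species": [68, 33],
        "species_share": [62.96, 30.56],
        "mean_abundance": [612.95, 130.22],
        "abundance_share": [79.17, 16.82],
    },
    index=pd.Index(["Calanoida", "Poecilostomatoida"], name="order"),
)

#: mean abundance of the two minor orders (their printed combined abundance
#: share is arithmetically inconsistent with these values and is therefore
#: not carried here)
MINOR_ORDER_MEANS = {"Cyclopoida": 24.31, "Harpacticoida": 8.70}

#: reported range of per-station total abundance, ind m^-3
STATION_TOTAL_RANGE = (279.08, 1510.19)


def _load(name: str) -> pd.DataFrame:
    with resources.files("copeind.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, index_col=0)


def load_dominance_reference() -> pd.DataFrame:
    """Dominant-taxon MA / RA / OR reference table (taxon-indexed)."""
    return _load("dominance_reference.csv")


@dataclasses.dataclass(frozen=True)
class IndicatorReference:
    """Printed indicator table split into aligned abundance / IndVal
    frames (taxa x groups, NaN where the source printed nothing)."""

    abundances: pd.DataFrame
    indvals: pd.DataFrame

    @property
    def groups(self) -> list[str]:
        return list(self.abundances.columns)


def load_indicator_reference() -> IndicatorReference:
    raw = _load("indicator_reference.csv")
    groups = sorted(
        {c.removeprefix("abundance_") for c in raw.columns if c.startswith("abundance_")}
    )
    ab = raw[[f"abundance_{g}" for g in groups]].copy()
    iv = raw[[f"indval_{g}" for g in groups]].copy()
    ab.columns = groups
    iv.columns = groups
    return IndicatorReference(abundances=ab, indvals=iv)
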