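"""Core domain containers for a station-by-taxon community survey.

All containers are thin, validated wrappers around :class:`pandas.DataFrame`
(or :class:`pandas.Series`), so downstream code can use ordinary pandas
operations while constructors enforce the contracts the analysis relies on:
non-negative finite abundances, unique identifiers, environmental values in
physically sensible ranges, and a four-order copepod taxonomy.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: canonical column order for environmental tables
ENV_COLUMNS = ("temperature", "salinity", "dissolved_oxygen", "pH")

#: the copepod orders recognised by :class:`TaxonMeta`
COPEPOD_ORDERS = ("Calanoida", "Cyclopoida", "Harpacticoida", "Poecilostomatoida")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dupes = sorted(set(index[index.duplicated()].astype(str)))
        raise SchemaError(f"duplicate {what} identifiers: {dupes}")


@dataclasses.dataclass(frozen=True)
class AbundanceMatrix:
    """Stations x taxa abundance matrix, individuals per cubic metre.

    Rows are stations, columns taxa; values must be finite and >= 0.
    Row and column order are preserved exactly as supplied.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise SchemaError("AbundanceMatrix expects a pandas DataFrame")
        _check_unique(df.index, "station")
        _check_unique(df.columns, "taxon")
        if df.shape[0] < 2:
            raise ValidationError("abundance matrix needs at least 2 stations")
        if df.shape[1] < 1:
            raise ValidationError("abundance matrix needs at least 1 taxon")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            # locate first non-numeric cell for a precise message
            for s in df.index:
                for t in df.columns:
                    try:
                        float(df.at[s, t])
                    except (TypeError, ValueError):
                        raise ValidationError(
                            f"non-numeric abundance at station {s!r}, taxon {t!r}:"
                            f" {df.at[s, t]!r}"
                        ) from None
            raise ValidationError("abundance matrix is not numeric")
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid abundance at station {df.index[i]!r}, taxon "
                f"{df.columns[j]!r}: {values[i, j]!r} (must be finite and >= 0)"
            )

    @property
    def station_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns.astype(str))

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_stations(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def select_taxa(self, taxa: Sequence[str]) -> "AbundanceMatrix":
        """Sub-matrix restricted to ``taxa`` (order as given)."""
        missing = [t for t in taxa if t not in self.data.columns]
        if missing:
            raise ValidationError(f"taxa not in abundance matrix: {missing}")
        return AbundanceMatrix(self.data.loc[:, list(taxa)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AbundanceMatrix) and self.data.equals(other.data)


@dataclasses.dataclass(frozen=True)
class EnvTable:
    """Per-station surface hydrography: temperature (degC), salinity (PSU),
    dissolved oxygen (mg/L) and pH."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "station")
        missing = [c for c in ENV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"environment table missing columns: {missing}")
        extra = [c for c in df.columns if c not in ENV_COLUMNS]
        if extra:
            raise SchemaError(f"environment table has unknown columns: {extra}")
        # canonicalise column order without copying data unnecessarily
        object.__setattr__(self, "data", df.loc[:, list(ENV_COLUMNS)])
        df = self.data
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number) or not np.isfinite(values).all():
            raise ValidationError("environment table must be numeric and finite")
        checks = {
            "temperature": (df["temperature"] > 0, "must be > 0 degC"),
            "salinity": (df["salinity"] > 0, "must be > 0 PSU"),
            "dissolved_oxygen": (df["dissolved_oxygen"] >= 0, "must be >= 0 mg/L"),
            "pH": ((df["pH"] > 0) & (df["pH"] < 14), "must lie in (0, 14)"),
        }
        for col, (ok, msg) in checks.items():
            if not ok.all():
                st = df.index[~ok][0]
                raise ValidationError(
                    f"{col} out of range at station {st!r}: {df.at[st, col]} ({msg})"
                )

    @property
    def station_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EnvTable) and self.data.equals(other.data)


@dataclasses.dataclass(frozen=True)
class TaxonMeta:
    """Taxon -> copepod order mapping plus a copepodite flag.

    Copepodite categories count toward abundance but not toward species
    number.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "taxon")
        missing = [c for c in ("order", "is_copepodite") if c not in df.columns]
        if missing:
            raise SchemaError(f"taxon table missing columns: {missing}")
        bad_orders = set(df["order"]) - set(COPEPOD_ORDERS)
        if bad_orders:
            raise SchemaError(
                f"unknown copepod order(s) {sorted(bad_orders)}; "
                f"expected one of {list(COPEPOD_ORDERS)}"
            )
        flags = df["is_copepodite"]
        if not all(isinstance(v, (bool, np.bool_)) for v in flags):
            raise SchemaError("is_copepodite must be boolean")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def species_ids(self) -> list[str]:
        """Taxa identified to species level (copepodites excluded)."""
        return list(self.data.index[~self.data["is_copepodite"]].astype(str))

    def order_of(self, taxon: str) -> str:
        return str(self.data.at[taxon, "order"])

    def require_covers(self, abund: AbundanceMatrix) -> None:
        unmapped = [t for t in abund.taxon_ids if t not in self.data.index]
        if unmapped:
            raise ValidationError(f"taxa without metadata: {unmapped}")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonMeta) and self.data.equals(other.data)


@dataclasses.dataclass(frozen=True)
class GroupPartition:
    """Assignment of every station to exactly one group."""

    labels: pd.Series  # index: station id, values: group label (str)

    def __post_init__(self) -> None:
        s = self.labels
        _check_unique(s.index, "station")
        if s.isna().any():
            st = s.index[s.isna()][0]
            raise ValidationError(f"station {st!r} has no group label")
        if len(s) == 0:
            raise ValidationError("partition is empty")
        object.__setattr__(self, "labels", s.astype(str))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "GroupPartition":
        return cls(pd.Series(dict(mapping), dtype=object))

    @property
    def station_ids(self) -> list[str]:
        return list(self.labels.index.astype(str))

    @property
    def group_labels(self) -> list[str]:
        """Distinct group labels, sorted."""
        return sorted(set(self.labels))

    @property
    def group_sizes(self) -> pd.Series:
        """Number of stations per group (Nsite_j)."""
        return self.labels.value_counts().sort_index()

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def members(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group].astype(str))

    def indicator_matrix(self, station_order: Sequence[str]) -> pd.DataFrame:
        """Stations x groups 0/1 membership matrix in ``station_order``."""
        labels = self.labels.reindex(list(station_order))
        if labels.isna().any():
            missing = [s for s in station_order if s not in self.labels.index]
            raise ValidationError(f"stations without group label: {missing}")
        return pd.get_dummies(labels).astype(float)

    def same_groups(self, other: "GroupPartition") -> bool:
        """True when the two partitions induce identical station groupings,
        irrespective of how the groups are named (Rand index = 1)."""
        if set(self.station_ids) != set(other.station_ids):
            return False
        a = self.labels
        b = other.labels.reindex(a.index)
        tab = pd.crosstab(a, b).to_numpy()
        return ((tab > 0).sum(axis=0) == 1).all() and ((tab > 0).sum(axis=1) == 1).all()


def validate_joint(
    abund: AbundanceMatrix | None = None,
    env: EnvTable | None = None,
    taxa: TaxonMeta | None = None,
    partition: GroupPartition | None = None,
) -> None:
    """Cross-table consistency: identical station sets, full taxon coverage."""
    tables = {}
    if abund is not None:
        tables["abundance"] = set(abund.station_ids)
    if env is not None:
        tables["environment"] = set(env.station_ids)
    if partition is not None:
        tables["partition"] = set(partition.station_ids)
    names = list(tables)
    for a, b in zip(names, names[1:]):
        if tables[a] != tables[b]:
            only_a = sorted(tables[a] - tables[b])
            only_b = sorted(tables[b] - tables[a])
            raise ValidationError(
                f"station sets differ between {a} and {b}: "
                f"only in {a}: {only_a}; only in {b}: {only_b}"
            )
    if taxa is not None and abund is not None:
        taxa.require_covers(abund)
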