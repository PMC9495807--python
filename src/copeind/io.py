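"""CSV readers and writers for the three survey input tables.

Dialect: comma-separated, UTF-8, ``.`` decimal separator, mandatory header.
The first column holds the station (or taxon) identifier; identifiers are
opaque, case-sensitive strings.  Missing cells are an error — there is no
imputation.  ``read(write(x)) == x`` exactly (pandas writes shortest
round-trip float representations).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, EnvTable, TaxonMeta, GroupPartition
from .errors import SchemaError, ValidationError

_BOOL_STRINGS = {
    "true": True, "false": False, "True": True, "False": False,
    "1": True, "0": False,
}


def _read_header(path: Path) -> list[str]:
    with open(path, newline="", encoding="utf-8") as fh:
        try:
            header = next(csv.reader(fh))
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
    return header


def _read_indexed_csv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    header = _read_header(path)
    if len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise SchemaError(f"{path}: duplicate column names {dupes}")
    df = pd.read_csv(path, index_col=0, dtype=object, keep_default_na=False,
                     na_values=[""])
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValidationError(f"{path}: missing {what} cell at row {row!r}, "
                              f"column {col!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _to_numeric(df: pd.DataFrame, path: Path, what: str) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            row = df.index[converted.isna()][0]
            raise ValidationError(
                f"{path}: non-numeric {what} at row {row!r}, column {col!r}: "
                f"{df.at[row, col]!r}"
            )
        # astype(float) goes through Python's correctly-rounded parser, so
        # write->read round-trips bit-exactly (pandas' fast parser does not)
        out[col] = df[col].astype(float)
    return pd.DataFrame(out, index=df.index)


def read_abundance(path: str | Path) -> AbundanceMatrix:
    """Read a station x taxon abundance CSV (header row = taxon names)."""
    path = Path(path)
    df = _read_indexed_csv(path, "abundance")
    df = _to_numeric(df, path, "abundance")
    try:
        return AbundanceMatrix(df)
    except ValidationError as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_abundance(abund: AbundanceMatrix, path: str | Path) -> None:
    df = abund.data.copy()
    df.index.name = df.index.name or "station"
    df.to_csv(path)


def read_env(path: str | Path) -> EnvTable:
    """Read a station x environment CSV (temperature, salinity,
    dissolved_oxygen, pH)."""
    path = Path(path)
    df = _read_indexed_csv(path, "environment")
    df = _to_numeric(df, path, "environment")
    try:
        return EnvTable(df)
    except ValidationError as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_env(env: EnvTable, path: str | Path) -> None:
    df = env.data.copy()
    df.index.name = df.index.name or "station"
    df.to_csv(path)


def read_taxa(path: str | Path) -> TaxonMeta:
    """Read a taxon metadata CSV with columns ``order`` and
    ``is_copepodite``."""
    path = Path(path)
    df = _read_indexed_csv(path, "taxon metadata")
    for col in ("order", "is_copepodite"):
        if col not in df.columns:
            raise SchemaError(f"{path}: taxon table missing column {col!r}")
    flags = []
    for taxon, raw in df["is_copepodite"].items():
        if raw not in _BOOL_STRINGS:
            raise SchemaError(
                f"{path}: is_copepodite for taxon {taxon!r} must be "
                f"true/false, got {raw!r}"
            )
        flags.append(_BOOL_STRINGS[raw])
    out = pd.DataFrame(
        {"order": df["order"].astype(str), "is_copepodite": np.array(flags)},
        index=df.index,
    )
    try:
        return TaxonMeta(out)
    except ValidationError as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_taxa(taxa: TaxonMeta, path: str | Path) -> None:
    df = taxa.data.copy()
    df.index.name = df.index.name or "taxon"
    df.to_csv(path)


def read_partition(path: str | Path) -> GroupPartition:
    path = Path(path)
    df = _read_indexed_csv(path, "partition")
    if "group" not in df.columns:
        raise SchemaError(f"{path}: partition table missing column 'group'")
    return GroupPartition(df["group"].astype(str))


def write_partition(partition: GroupPartition, path: str | Path) -> None:
    df = pd.DataFrame({"group": partition.labels})
    df.index.name = "station"
    df.to_csv(path)
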