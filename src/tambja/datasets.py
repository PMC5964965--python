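"""Compound tables and descriptor matrices.

The central container is :class:`CompoundTable`, a validated wrapper around a
pandas DataFrame holding one row per compound: chloride-transport activity
(EC50 in mol% carrier/lipid, Hill coefficient n, initial efflux rate k_ini in
% s^-1), predicted lipophilicity (ALOGPs), HPLC retention time in minutes,
and optional substituent annotations (ring substituent R4, enamine
substituent R5, R6 substituent class).

A 43-compound measurement table for the tambjamine anion-carrier series is
packaged as the fixture ``"table1"``; compound 43's EC50 is flagged as
imputed (derived from its initial rate rather than a Hill analysis) so
downstream fits can include or exclude it explicitly.

CSV conventions: comma-separated, UTF-8, mandatory header, ``.`` decimal
point; an empty cell or the literal ``NA`` means missing.  The token
``n.d.`` (not determined) is accepted on input for the retention-time column
and normalised to missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "CompoundTable",
    "load_compound_table",
    "load_table1",
    "write_compound_table",
    "load_descriptor_matrix",
    "validate_table",
]

#: Required columns of a compound CSV, in schema order.
COMPOUND_COLUMNS = [
    "compound_id",
    "ec50_molpct",
    "hill_n",
    "kini_pct_per_s",
    "alogps",
    "rt_min",
    "r4",
    "r5",
    "r6_class",
    "ec50_imputed",
]

_NUMERIC_COLUMNS = ["ec50_molpct", "hill_n", "kini_pct_per_s", "alogps", "rt_min"]
_LABEL_COLUMNS = ["r4", "r5", "r6_class"]
_MISSING_TOKENS = {"", "NA", "n.d.", "nan"}
_TRUE_TOKENS = {"true", "1", "yes"}
_FALSE_TOKENS = {"false", "0", "no", ""}


@dataclass
class CompoundTable:
    """An ordered collection of compound records plus a provenance tag.

    ``data`` holds one row per compound with the columns of
    :data:`COMPOUND_COLUMNS`; missing numeric values are NaN, missing labels
    are ``None``, and ``ec50_imputed`` is boolean.
    """

    data: pd.DataFrame
    provenance: str = "user"

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return f"CompoundTable(n={len(self)}, provenance={self.provenance!r})"

    def record(self, compound_id: str) -> pd.Series:
        """Return the row for one compound id."""
        hit = self.data[self.data["compound_id"] == str(compound_id)]
        if hit.empty:
            raise KeyError(f"no compound with id {compound_id!r}")
        return hit.iloc[0]

    def log_potency(self) -> pd.Series:
        """log10(1/EC50), the response modelled throughout the package."""
        return -np.log10(self.data["ec50_molpct"].astype(float))

    def subset(self, mask) -> "CompoundTable":
        return CompoundTable(self.data[mask].reset_index(drop=True), self.provenance)

    def without_imputed(self) -> "CompoundTable":
        """Drop records whose EC50 was imputed rather than measured."""
        return self.subset(~self.data["ec50_imputed"])

    def validate(self) -> list[str]:
        return validate_table(self)


def _parse_numeric(raw: pd.Series, column: str) -> pd.Series:
    out = np.full(len(raw), np.nan)
    for i, value in enumerate(raw):
        token = "" if value is None else str(value).strip()
        if token in _MISSING_TOKENS:
            continue
        try:
            out[i] = float(token)
        except ValueError:
            raise SchemaError(
                f"unparseable numeric value {token!r} in column {column!r}, row {i + 2}"
            ) from None
    return pd.Series(out, name=column)


def _parse_label(raw: pd.Series, column: str) -> pd.Series:
    vals = [
        None if (v is None or str(v).strip() in _MISSING_TOKENS) else str(v).strip()
        for v in raw
    ]
    return pd.Series(vals, name=column, dtype=object)


def _parse_bool(raw: pd.Series, column: str) -> pd.Series:
    out = []
    for i, value in enumerate(raw):
        token = ("" if value is None else str(value).strip()).lower()
        if token in _TRUE_TOKENS:
            out.append(True)
        elif token in _FALSE_TOKENS:
            out.append(False)
        else:
            raise SchemaError(
                f"unparseable boolean {token!r} in column {column!r}, row {i + 2}"
            )
    return pd.Series(out, name=column, dtype=bool)


def load_compound_table(path_or_fixture) -> CompoundTable:
    """Load a compound CSV, or the packaged fixture named ``"table1"``.

    Validates the schema (raising :class:`SchemaError` naming any missing
    column or unparseable cell), normalises ``n.d.``/empty/``NA`` to missing,
    and preserves the imputed flag on EC50 values.
    """
    if isinstance(path_or_fixture, str) and path_or_fixture == "table1":
        return load_table1()
    path = Path(path_or_fixture)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty compound file: {path}") from None
    return _table_from_raw(raw, provenance=str(path))


def load_table1() -> CompoundTable:
    """The packaged 43-compound tambjamine transport dataset."""
    with resources.files("tambja.data").joinpath("table1.csv").open("r") as fh:
        raw = pd.read_csv(fh, dtype=str, keep_default_na=False)
    return _table_from_raw(raw, provenance="table1")


def _table_from_raw(raw: pd.DataFrame, provenance: str) -> CompoundTable:
    missing = [c for c in COMPOUND_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    cols = {"compound_id": _parse_label(raw["compound_id"], "compound_id")}
    if cols["compound_id"].isna().any():
        raise SchemaError("compound_id must not be missing")
    for c in _NUMERIC_COLUMNS:
        cols[c] = _parse_numeric(raw[c], c)
    for c in _LABEL_COLUMNS:
        cols[c] = _parse_label(raw[c], c)
    cols["ec50_imputed"] = _parse_bool(raw["ec50_imputed"], "ec50_imputed")
    return CompoundTable(pd.DataFrame(cols), provenance)


def write_compound_table(table: CompoundTable, path) -> None:
    """Write a compound table in the package CSV dialect (round-trip safe)."""
    df = table.data.copy()
    for c in _NUMERIC_COLUMNS:
        df[c] = [("" if np.isnan(v) else repr(float(v))) for v in df[c]]
    for c in _LABEL_COLUMNS:
        df[c] = ["" if v is None else v for v in df[c]]
    df["ec50_imputed"] = ["true" if v else "false" for v in df["ec50_imputed"]]
    df[COMPOUND_COLUMNS].to_csv(path, index=False)


def validate_table(table: CompoundTable) -> list[str]:
    """Check record invariants; returns a list of violations (empty = valid)."""
    df = table.data
    report: list[str] = []
    dup = df["compound_id"][df["compound_id"].duplicated()]
    for cid in dup.unique():
        report.append(f"duplicate id {cid!r}")
    for _, row in df.iterrows():
        cid = row["compound_id"]
        if not np.isnan(row["ec50_molpct"]) and row["ec50_molpct"] <= 0:
            report.append(f"compound {cid}: ec50 must be positive")
        if np.isnan(row["ec50_molpct"]):
            report.append(f"compound {cid}: ec50 is required")
        if not np.isnan(row["kini_pct_per_s"]) and row["kini_pct_per_s"] <= 0:
            report.append(f"compound {cid}: kini must be positive")
        if np.isnan(row["kini_pct_per_s"]):
            report.append(f"compound {cid}: kini is required")
        if not np.isnan(row["hill_n"]) and row["hill_n"] <= 0:
            report.append(f"compound {cid}: hill_n must be positive when present")
    return report


def load_descriptor_matrix(path) -> pd.DataFrame:
    """Load a descriptor CSV (compound_id column + one column per descriptor).

    Values are kept as-is (possibly strings); cleaning and numeric coercion
    are the job of :func:`tambja.descriptors.clean_descriptors`.  The result
    is indexed by compound id with unique descriptor columns.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty descriptor file: {path}") from None
    if "compound_id" not in df.columns:
        raise SchemaError("missing required column(s): compound_id")
    if df.columns.duplicated().any():
        raise SchemaError("descriptor column names must be unique")
    df = df.set_index("compound_id")
    df = df.replace({t: np.nan for t in _MISSING_TOKENS if t})
    df = df.replace("", np.nan)
    out = {}
    for c in df.columns:
        try:
            out[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            out[c] = df[c]
    return pd.DataFrame(out, index=df.index)
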