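"""Shared data model and tabular I/O for the ring-trial pipeline.

The central container is :class:`MeasurementTable`, a validated long-format
pandas DataFrame holding replicate-level metabolite measurements across
platforms and shipments.  Missing values are carried as an explicit
``missing`` flag (value ``NaN``), never as zero or a sentinel: downstream
stages must see missingness, not a substituted number.

Absolute-unit platforms report µM; relative-unit (discovery) platforms keep
an arbitrary scale and are tagged ``unit_kind="relative"`` so that accuracy
scoring against certified reference concentrations can exclude them.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "UNIT_KINDS",
    "DILUTION_FRACTIONS",
    "MEASUREMENT_COLUMNS",
    "SchemaError",
    "ValidationError",
    "ReferenceCOA",
    "MeasurementTable",
    "read_measurements",
    "read_coa",
    "read_harmonization_map",
    "read_dilution_design",
    "write_table",
    "packaged_coa_path",
    "packaged_reported_path",
]

#: Biological / reference sample groups.
PTSD = "PTSD"
CONTROL = "CONTROL"
NIST = "NIST"
NIST_DILUTION = "NIST_DILUTION"
GROUPS = (PTSD, CONTROL, NIST, NIST_DILUTION)

#: Groups that take part in missingness filtering and precision summaries.
BIOLOGICAL_GROUPS = (PTSD, CONTROL)

ABSOLUTE_UM = "absolute_uM"
RELATIVE = "relative"
UNIT_KINDS = (ABSOLUTE_UM, RELATIVE)

#: Nominal dilution-curve design points (fraction of full concentration).
DILUTION_FRACTIONS = (1.0, 0.8, 0.6, 0.4)

MEASUREMENT_COLUMNS = [
    "platform",
    "shipment",
    "sample_id",
    "parent_sample_id",
    "replicate_slot",
    "group",
    "dilution_fraction",
    "metabolite",
    "value",
    "unit_kind",
    "imputed_by_vendor",
    "missing",
]

MEASUREMENT_KEY = ["platform", "shipment", "sample_id", "metabolite"]


class SchemaError(ValueError):
    """A mandatory column is absent or unresolvable."""


class ValidationError(ValueError):
    """One or more rows violate a table invariant; message names the rows."""


@dataclasses.dataclass(frozen=True)
class ReferenceCOA:
    """One certified analyte concentration from a Certificate of Analysis."""

    analyte: str
    coa_value: float  # µM, > 0
    hmdb_id: str | None = None


def packaged_coa_path() -> Path:
    """Path to the packaged NIST SRM 1950 COA concentration fixture."""
    return Path(str(importlib.resources.files("ringtrial") / "data" / "nist_srm1950_coa.csv"))


def packaged_reported_path() -> Path:
    """Path to the packaged per-platform reported SRM 1950 values fixture."""
    return Path(str(importlib.resources.files("ringtrial") / "data" / "srm1950_reported.csv"))


def _check_rows(df: pd.DataFrame) -> list[str]:
    """Return row-indexed diagnostics for every invariant violation."""
    diags: list[str] = []

    def bad(mask: pd.Series, what: str) -> None:
        for idx in df.index[mask.fillna(False)]:
            diags.append(f"row {idx}: {what}")

    bad(~df["group"].isin(GROUPS), f"group not one of {GROUPS}")
    bad(~df["shipment"].isin([1, 2]), "shipment must be 1 or 2")
    bad(~df["unit_kind"].isin(UNIT_KINDS), f"unit_kind not one of {UNIT_KINDS}")
    bad(~df["missing"] & df["value"].isna(), "missing=False but value absent")
    bad(df["missing"] & df["value"].notna(), "missing=True but value present")
    bad(df["value"].notna() & (df["value"] < 0), "negative value")
    dil = df["group"].eq(NIST_DILUTION)
    ok_frac = df["dilution_fraction"].round(6).isin([round(f, 6) for f in DILUTION_FRACTIONS])
    bad(dil & ~ok_frac, f"dilution_fraction must be one of {DILUTION_FRACTIONS}")

    dup = df.duplicated(subset=MEASUREMENT_KEY, keep=False)
    if dup.any():
        keys = df.loc[dup, MEASUREMENT_KEY].drop_duplicates().itertuples(index=False)
        for k in keys:
            diags.append(f"duplicate key {tuple(k)}")
    return diags


class MeasurementTable:
    """Validated long-format replicate-level measurement table.

    Parameters
    ----------
    df:
        Frame with the :data:`MEASUREMENT_COLUMNS` layout.  A ``missing``
        column is derived from absent values when not supplied.
    strict:
        If true (default), any invariant violation raises
        :class:`ValidationError`; otherwise offending rows are dropped and
        recorded in :attr:`diagnostics` (rows are never silently lost:
        ``len(input) == len(table) + len(diagnostics)``).
    """

    def __init__(self, df: pd.DataFrame, *, strict: bool = True, validate: bool = True):
        df = df.copy()
        required = [c for c in MEASUREMENT_COLUMNS if c not in ("missing", "imputed_by_vendor", "dilution_fraction")]
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"missing mandatory column(s): {missing_cols}")
        if "dilution_fraction" not in df.columns:
            df["dilution_fraction"] = np.nan
        if "imputed_by_vendor" not in df.columns:
            # The flag is carried per cell but vendors rarely disclose it.
            df["imputed_by_vendor"] = False
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        if "missing" not in df.columns:
            df["missing"] = df["value"].isna()
        df["missing"] = df["missing"].astype(bool)
        df["imputed_by_vendor"] = df["imputed_by_vendor"].astype(bool)
        df["shipment"] = pd.to_numeric(df["shipment"], errors="raise")
        df = df[MEASUREMENT_COLUMNS + [c for c in df.columns if c not in MEASUREMENT_COLUMNS]]

        self.diagnostics: list[str] = []
        if validate:
            diags = _check_rows(df)
            if diags and strict:
                raise ValidationError("; ".join(diags))
            if diags:
                bad_rows = {int(d.split()[1].rstrip(":")) for d in diags if d.startswith("row ")}
                dup = df.duplicated(subset=MEASUREMENT_KEY, keep=False)
                keep = ~df.index.isin(bad_rows) & ~dup
                self.diagnostics = diags
                df = df[keep]
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        a = self.df[MEASUREMENT_COLUMNS].reset_index(drop=True)
        b = other.df[MEASUREMENT_COLUMNS].reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True

    @property
    def platforms(self) -> list[str]:
        return sorted(self.df["platform"].unique())

    @property
    def shipments(self) -> list[int]:
        return sorted(int(s) for s in self.df["shipment"].unique())

    def subset(self, **where) -> pd.DataFrame:
        """Rows matching the given column==value constraints."""
        mask = pd.Series(True, index=self.df.index)
        for col, val in where.items():
            mask &= self.df[col] == val
        return self.df[mask]

    def to_csv(self, path: str | Path) -> None:
        self.df[MEASUREMENT_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "MeasurementTable":
        return cls(df, **kw)


def read_measurements(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    strict: bool = True,
) -> MeasurementTable:
    """Read a long-format measurement CSV/TSV into a validated table.

    ``dialect`` maps file column names to the canonical names, e.g.
    ``{"vendor": "platform"}``; resolution is exact-match only (no fuzzy
    matching) so that two runs over the same file always agree.
    Vendor-imputed values, where flagged, pass through unmodified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if dialect:
        df = df.rename(columns=dict(dialect))
    return MeasurementTable(df, strict=strict)


def read_coa(path: str | Path | None = None) -> list[ReferenceCOA]:
    """Read a Certificate-of-Analysis concentration table.

    With no ``path`` the packaged NIST SRM 1950 fixture is used.  Values must
    be strictly positive µM; a non-positive value raises
    :class:`ValidationError`.  An empty file yields an empty list with a
    warning.
    """
    if path is None:
        path = packaged_coa_path()
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"COA table {path} contains no analytes", stacklevel=2)
        return []
    if "analyte" not in df.columns:
        raise SchemaError("COA table needs an 'analyte' column")
    value_col = next((c for c in ("coa_uM", "coa_value", "value") if c in df.columns), None)
    if value_col is None:
        raise SchemaError("COA table needs a concentration column (coa_uM)")
    vals = pd.to_numeric(df[value_col], errors="raise")
    if (vals <= 0).any():
        bad = df.loc[vals <= 0, "analyte"].tolist()
        raise ValidationError(f"non-positive COA value for {bad}")
    if df["analyte"].duplicated().any():
        dup = df.loc[df["analyte"].duplicated(), "analyte"].tolist()
        raise ValidationError(f"duplicate COA analyte(s): {dup}")
    hmdb = df["hmdb_id"] if "hmdb_id" in df.columns else pd.Series([None] * len(df))
    return [
        ReferenceCOA(analyte=a, coa_value=float(v), hmdb_id=(h if isinstance(h, str) and h else None))
        for a, v, h in zip(df["analyte"], vals, hmdb)
    ]


def read_harmonization_map(path: str | Path) -> pd.DataFrame:
    """Read a raw-name→HMDB-ID→class map (TSV or CSV).

    Columns: platform, raw_name, hmdb_id (may be blank), class_label.
    ``mapped`` is derived: true iff hmdb_id is present.  (platform, raw_name)
    must be unique.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("platform", "raw_name", "class_label"):
        if col not in df.columns:
            raise SchemaError(f"harmonization map needs column '{col}'")
    if "hmdb_id" not in df.columns:
        df["hmdb_id"] = None
    df["hmdb_id"] = df["hmdb_id"].where(df["hmdb_id"].notna() & (df["hmdb_id"] != ""), None)
    df["mapped"] = df["hmdb_id"].notna()
    if df.duplicated(subset=["platform", "raw_name"]).any():
        dup = df.loc[df.duplicated(subset=["platform", "raw_name"]), ["platform", "raw_name"]]
        raise ValidationError(f"duplicate (platform, raw_name) rows: {dup.values.tolist()}")
    return df.reset_index(drop=True)


def read_dilution_design(path: str | Path) -> dict[str, float]:
    """Read a sample_id→nominal dilution fraction design table (CSV)."""
    df = pd.read_csv(path)
    for col in ("sample_id", "dilution_fraction"):
        if col not in df.columns:
            raise SchemaError(f"dilution design needs column '{col}'")
    fracs = pd.to_numeric(df["dilution_fraction"], errors="raise")
    if ((fracs <= 0) | (fracs > 1)).any():
        raise ValidationError("dilution fractions must lie in (0, 1]")
    return dict(zip(df["sample_id"].astype(str), fracs.astype(float)))


def _records_to_frame(records: Iterable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = list(records)
    if rows and dataclasses.is_dataclass(rows[0]):
        return pd.DataFrame([dataclasses.asdict(r) for r in rows])
    return pd.DataFrame(rows)


def write_table(
    records: Sequence | pd.DataFrame,
    path: str | Path,
    format: str = "csv",
    columns: Sequence[str] | None = None,
) -> Path:
    """Write records (dataclasses, dicts or a DataFrame) to CSV or JSON.

    CSV output keeps a fixed column order so write→read round-trips
    field-wise; an empty record list yields a header-only file when
    ``columns`` is given.
    """
    path = Path(path)
    df = _records_to_frame(records)
    if columns is not None:
        for c in columns:
            if c not in df.columns:
                df[c] = pd.Series(dtype=object)
        df = df[list(columns)]
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        df.to_json(path, orient="records", indent=1)
    else:
        raise ValueError(f"unknown format {format!r} (use 'csv' or 'json')")
    return path
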