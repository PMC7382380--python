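"""Domain types, CSV schema, validation and round-trip I/O for plant-organ tables.

The unit of observation is one organ of one plant: an aboveground
*Arabidopsis* plant is separated at maturity into rosette, stem (stem +
cauline leaves + empty siliques) and total seeds; roots are not harvested,
so the data model is strictly three-compartment.  Each row carries dry
weight (mg), total N and C concentrations (percent of dry weight) and,
for tracer-labelled plants, the ¹⁵N atom percent A% = 100·¹⁵N/(¹⁵N+¹⁴N).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ORGANS = ("rosette", "stem", "seeds")
CONDITIONS = ("control", "drought", "lowN", "defense", "dark", "heat")
DEFAULT_GENOTYPES = ("7", "63", "83", "134", "359", "397", "401", "442")

#: ¹⁵N atom percent of unlabelled plant material (natural abundance).
NATURAL_ABUNDANCE_A15 = 0.3660

#: Exact CSV header for plant-organ tables.
CSV_COLUMNS = [
    "plant_id",
    "genotype",
    "condition",
    "experiment",
    "organ",
    "dw_mg",
    "n_pct",
    "c_pct",
    "a15_pct",
]

_LABEL_COLUMNS = ["plant_id", "genotype", "condition", "experiment", "organ"]
_NUMERIC_COLUMNS = ["dw_mg", "n_pct", "c_pct", "a15_pct"]


class NuetraceError(Exception):
    """Base class for all package errors."""


class SchemaError(NuetraceError):
    """The table does not have the expected columns."""


class ParseError(NuetraceError):
    """A cell that must be numeric could not be parsed."""


class ValidationError(NuetraceError):
    """A row violates a typed bound or invariant."""


class IntegrityError(NuetraceError):
    """Duplicate or mutually inconsistent rows."""


@dataclass(frozen=True)
class OrganRecord:
    """One organ of one plant."""

    plant_id: str
    genotype: str
    condition: str
    experiment: str
    organ: str
    dw_mg: float
    n_pct: float
    c_pct: float
    a15_pct: float | None = None

    def as_row(self) -> dict:
        return {
            "plant_id": self.plant_id,
            "genotype": self.genotype,
            "condition": self.condition,
            "experiment": self.experiment,
            "organ": self.organ,
            "dw_mg": self.dw_mg,
            "n_pct": self.n_pct,
            "c_pct": self.c_pct,
            "a15_pct": np.nan if self.a15_pct is None else self.a15_pct,
        }


@dataclass
class Dataset:
    """A validated plant-organ table plus the natural-abundance baseline.

    Parameters
    ----------
    records : pandas.DataFrame
        One row per (plant, organ); columns as in :data:`CSV_COLUMNS`.
    a15_control_pct : float
        Atom percent ¹⁵N of unlabelled control material, used as the
        baseline when converting A% to enrichment E%.
    """

    records: pd.DataFrame
    a15_control_pct: float = NATURAL_ABUNDANCE_A15
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.records = validate_records(self.records)

    @classmethod
    def from_records(
        cls, records: list[OrganRecord], a15_control_pct: float = NATURAL_ABUNDANCE_A15
    ) -> "Dataset":
        return cls(pd.DataFrame([r.as_row() for r in records]), a15_control_pct)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def plant_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["plant_id"]))

    def complete_plants(self) -> list[str]:
        """Plants with all three organs present (the only ones indexed)."""
        counts = self.records.groupby("plant_id", sort=False)["organ"].nunique()
        return list(counts.index[counts == len(ORGANS)])

    def iter_plants(self):
        """Yield ``(plant_id, frame)`` for every complete plant."""
        complete = set(self.complete_plants())
        for pid, grp in self.records.groupby("plant_id", sort=False):
            if pid in complete:
                yield pid, grp

    def seeds(self) -> pd.DataFrame:
        """Seed rows only (used for C:N stoichiometry)."""
        return self.records[self.records["organ"] == "seeds"].reset_index(drop=True)

    def write(self, path: str | os.PathLike) -> None:
        write_results(self.records, path)


def _require_columns(df: pd.DataFrame) -> None:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s): {', '.join(missing)}; "
            f"expected header {','.join(CSV_COLUMNS)}"
        )


def validate_records(df: pd.DataFrame, *, row_offset: int = 0) -> pd.DataFrame:
    """Validate a plant-organ frame, returning a typed copy.

    Rows are addressed by their 0-based position plus ``row_offset``
    (readers pass 2 so messages point at physical CSV lines).  All
    violations of one category are reported together; nothing is ever
    silently dropped.
    """
    _require_columns(df)
    df = df.copy().reset_index(drop=True)
    for col in _LABEL_COLUMNS:
        df[col] = df[col].astype(str).str.strip()

    parse_msgs = []
    for col in _NUMERIC_COLUMNS:
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        blank = raw.isna() | (raw.astype(str).str.strip() == "")
        bad = coerced.isna() & ~blank
        for i in np.flatnonzero(bad.to_numpy()):
            parse_msgs.append(f"row {i + row_offset}: non-numeric {col}={raw.iloc[i]!r}")
        df[col] = coerced.astype(float)
    if parse_msgs:
        raise ParseError("; ".join(parse_msgs))

    msgs = []
    for i, row in df.iterrows():
        where = f"row {i + row_offset}"
        if row["organ"] not in ORGANS:
            msgs.append(f"{where}: organ must be one of {ORGANS}, got {row['organ']!r}")
        if np.isnan(row["dw_mg"]) or row["dw_mg"] < 0:
            msgs.append(f"{where}: dw_mg must be a number >= 0, got {row['dw_mg']}")
        for col in ("n_pct", "c_pct"):
            v = row[col]
            if np.isnan(v) or not (0.0 <= v <= 100.0):
                msgs.append(f"{where}: {col} must lie in [0, 100], got {v}")
        if not np.isnan(row["n_pct"]) and not np.isnan(row["c_pct"]):
            if row["n_pct"] + row["c_pct"] > 100.0 + 1e-9:
                msgs.append(
                    f"{where}: n_pct + c_pct = {row['n_pct'] + row['c_pct']:.4f} exceeds 100"
                )
        a15 = row["a15_pct"]
        if not np.isnan(a15) and not (0.0 <= a15 <= 100.0):
            msgs.append(f"{where}: a15_pct must lie in [0, 100], got {a15}")
    if msgs:
        raise ValidationError("; ".join(msgs))

    dup = df.duplicated(subset=["plant_id", "organ"], keep=False)
    if dup.any():
        pairs = sorted(
            set(map(tuple, df.loc[dup, ["plant_id", "organ"]].to_numpy()))
        )
        raise IntegrityError(
            "duplicate (plant_id, organ) pairs: "
            + "; ".join(f"({p}, {o})" for p, o in pairs)
        )

    labels = df.groupby("plant_id")[["genotype", "condition", "experiment"]].nunique()
    bad_plants = labels.index[(labels > 1).any(axis=1)]
    if len(bad_plants):
        raise IntegrityError(
            "inconsistent genotype/condition/experiment labels within plant(s): "
            + ", ".join(map(str, bad_plants))
        )
    return df


def read_dataset(
    path: str | os.PathLike,
    a15_control_pct: float = NATURAL_ABUNDANCE_A15,
) -> Dataset:
    """Read and validate a plant-organ CSV (UTF-8, comma-separated, '.' decimal)."""
    try:
        df = pd.read_csv(path, dtype={c: str for c in _LABEL_COLUMNS})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ParseError(f"could not parse {path}: {exc}") from exc
    # +2: one for the header line, one for 1-based file lines
    records = validate_records(df, row_offset=2)
    ds = Dataset.__new__(Dataset)
    ds.records = records
    ds.a15_control_pct = a15_control_pct
    ds.source = str(path)
    return ds


def write_results(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a derived table as CSV.

    Floats are written with 12 significant digits (read-back agrees to that
    precision), integers bit-identically, and NaN as the empty field.
    """
    table.to_csv(path, index=False, float_format="%.12g")


def read_results(path: str | os.PathLike, label_columns: list[str] | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    dtype = {c: str for c in (label_columns or _LABEL_COLUMNS)}
    df = pd.read_csv(path)
    for col, t in dtype.items():
        if col in df.columns:
            df[col] = df[col].astype(t)
    return df
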