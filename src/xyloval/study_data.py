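"""Data model and delimited-text I/O for the measurement tables.

Two table kinds flow through the pipeline:

* :class:`ReplicateTable` — long-format replicate measurements of
  controls, spiked buffer/urine levels and blanks, keyed by analyzer,
  matrix, level and run.  Concentrations are in mg/dL.
* :class:`PairedComparisonTable` — per-patient cumulated urinary xylose
  totals (mg) measured by the reference colorimetric (phloroglucinol)
  method and the candidate enzymatic method.

Readers auto-detect comma/tab/semicolon delimiters, require ``.`` as the
decimal separator (comma decimals are rejected loudly rather than
silently corrupted), and report invariant violations with the offending
row indices.  Writers emit RFC-4180-style CSV so that a write/read
round trip reproduces every field and the row order exactly.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

MATRICES = ("buffer", "urine", "water")
LACTASE_LABELS = ("hypolactasic", "normolactasic")

REPLICATE_COLUMNS = (
    "analyzer",
    "matrix",
    "level_id",
    "nominal_conc",
    "run_id",
    "replicate_index",
    "value",
    "raw_response",
)
#: columns that must be present in a replicate file (the rest are optional)
REPLICATE_REQUIRED = ("analyzer", "matrix", "level_id", "run_id", "replicate_index")

COMPARISON_COLUMNS = (
    "patient_id",
    "method_a_total",
    "method_b_total",
    "reference_label",
    "adjudicated_label",
)
COMPARISON_REQUIRED = ("patient_id", "method_a_total", "method_b_total")

_COMMA_DECIMAL = re.compile(r"^\s*-?\d+,\d+\s*$")


@dataclass(frozen=True)
class Measurement:
    """One replicate measurement.

    Exactly one of ``value`` (mg/dL concentration) and ``raw_response``
    (absorbance units) is present.
    """

    analyzer: str
    matrix: str
    level_id: str
    run_id: str
    replicate_index: int
    nominal_conc: float | None = None
    value: float | None = None
    raw_response: float | None = None


@dataclass
class ReplicateTable:
    """Validated long-format replicate measurements; units fixed to mg/dL."""

    df: pd.DataFrame
    units: str = "mg/dL"

    def __post_init__(self) -> None:
        self.df = _validate_replicates(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def values_for(self, level_id: str, analyzer: str | None = None) -> np.ndarray:
        """Measured concentrations for one level (optionally one analyzer)."""
        sub = self.df[self.df["level_id"] == level_id]
        if analyzer is not None:
            sub = sub[sub["analyzer"] == analyzer]
        return sub["value"].to_numpy(dtype=float)


@dataclass(frozen=True)
class PairedSample:
    """Per-patient totals (mg) for the two methods.

    ``method_a_total`` is the reference phloroglucinol result,
    ``method_b_total`` the candidate enzymatic result.  When an
    ``adjudicated_label`` is present it overrides ``reference_label``
    downstream.
    """

    patient_id: str
    method_a_total: float
    method_b_total: float
    reference_label: str | None = None
    adjudicated_label: str | None = None


@dataclass
class PairedComparisonTable:
    """Validated table of :class:`PairedSample` rows; patient_id unique."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _validate_comparison(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def method_a(self) -> np.ndarray:
        return self.df["method_a_total"].to_numpy(dtype=float)

    @property
    def method_b(self) -> np.ndarray:
        return self.df["method_b_total"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# validation


def _numeric(series: pd.Series, col: str, rows_offset: int = 0) -> pd.Series:
    """Coerce a column to float, rejecting comma decimals and garbage."""
    as_str = series.astype("string")
    bad_comma = as_str.str.match(_COMMA_DECIMAL.pattern, na=False)
    if bad_comma.any():
        rows = list(series.index[bad_comma])
        raise ParseError(
            f"column {col!r} uses ',' as decimal separator in rows {rows}; "
            "this reader requires '.' decimals — convert the file explicitly"
        )
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna() & (as_str.str.strip() != "")
    if bad.any():
        rows = list(series.index[bad])
        raise ParseError(f"column {col!r} is not numeric in rows {rows}")
    return out.astype(float)


def _validate_replicates(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REPLICATE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"replicate table is missing mandatory columns {missing}")
    if len(df) == 0:
        raise ValidationError("no data rows")
    df = df.copy()
    for col in ("nominal_conc", "value", "raw_response"):
        if col not in df.columns:
            df[col] = np.nan
        else:
            df[col] = _numeric(df[col], col)
    df["replicate_index"] = _numeric(df["replicate_index"], "replicate_index")
    for col in ("analyzer", "matrix", "level_id", "run_id"):
        df[col] = df[col].astype(str)

    problems: list[str] = []
    bad_matrix = ~df["matrix"].isin(MATRICES)
    if bad_matrix.any():
        problems.append(
            f"matrix outside {MATRICES} in rows {list(df.index[bad_matrix])}"
        )
    has_value = df["value"].notna()
    has_raw = df["raw_response"].notna()
    both = has_value & has_raw
    neither = ~has_value & ~has_raw
    if both.any():
        problems.append(
            f"both value and raw_response present in rows {list(df.index[both])}"
        )
    if neither.any():
        problems.append(
            f"neither value nor raw_response present in rows {list(df.index[neither])}"
        )
    negative = has_value & (df["value"] < 0)
    if negative.any():
        problems.append(f"negative value in rows {list(df.index[negative])}")
    dup = df.duplicated(
        subset=["analyzer", "level_id", "run_id", "replicate_index"], keep=False
    )
    if dup.any():
        problems.append(
            "replicate_index not unique within (analyzer, level_id, run_id) "
            f"in rows {list(df.index[dup])}"
        )
    if problems:
        raise ValidationError("; ".join(problems))
    return df


def _validate_comparison(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COMPARISON_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"comparison table is missing mandatory columns {missing}")
    if len(df) == 0:
        raise ValidationError("no data rows")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    for col in ("method_a_total", "method_b_total"):
        df[col] = _numeric(df[col], col)
        if df[col].isna().any():
            raise ValidationError(
                f"missing {col} in rows {list(df.index[df[col].isna()])}"
            )
        if (df[col] < 0).any():
            raise ValidationError(
                f"negative {col} in rows {list(df.index[df[col] < 0])}"
            )
    for col in ("reference_label", "adjudicated_label"):
        if col not in df.columns:
            df[col] = pd.Series([None] * len(df), dtype=object)
        else:
            df[col] = df[col].where(df[col].notna(), None)
            labelled = df[col].notna()
            bad = labelled & ~df[col].isin(LACTASE_LABELS)
            if bad.any():
                raise ValidationError(
                    f"{col} outside {LACTASE_LABELS} in rows {list(df.index[bad])}"
                )
    dup = df["patient_id"].duplicated(keep=False)
    if dup.any():
        ids = sorted(set(df.loc[dup, "patient_id"]))
        raise ValidationError(f"duplicate patient_id: {ids}", rows=list(df.index[dup]))
    return df


# ---------------------------------------------------------------------------
# I/O


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValidationError("no data rows")
    counts = {d: header.count(d) for d in (",", "\t", ";")}
    delim = max(counts, key=counts.get)
    if counts[delim] == 0:
        # single-column file; delimiter irrelevant
        return ","
    return delim


def _read_table(
    path: str | Path, column_map: Mapping[str, str] | None, dialect: str | None
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = dialect or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True, encoding="utf-8")
    if column_map:
        df = df.rename(columns=dict(column_map))
    return df


def read_replicates(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    dialect: str | None = None,
) -> ReplicateTable:
    """Read a replicate CSV/TSV into a validated :class:`ReplicateTable`.

    ``column_map`` maps file header names to the canonical field names;
    defaults assume the headers the synthetic generators emit.
    """
    return ReplicateTable(_read_table(path, column_map, dialect))


def read_comparison(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    dialect: str | None = None,
) -> PairedComparisonTable:
    """Read a paired-totals CSV/TSV into a :class:`PairedComparisonTable`."""
    return PairedComparisonTable(_read_table(path, column_map, dialect))


def _write(df: pd.DataFrame, path: str | Path, columns: Sequence[str]) -> None:
    out = df.copy()
    for col in columns:
        if col not in out.columns:
            out[col] = np.nan
    out[list(columns)].to_csv(
        path, index=False, quoting=csv.QUOTE_MINIMAL, encoding="utf-8"
    )


def write_replicates(table: ReplicateTable, path: str | Path) -> None:
    _write(table.df, path, REPLICATE_COLUMNS)


def write_comparison(table: PairedComparisonTable, path: str | Path) -> None:
    _write(table.df, path, COMPARISON_COLUMNS)


def total_from_concentration(conc_mg_dl: float, volume_dl: float) -> float:
    """Convenience: cumulated amount (mg) from concentration × urine volume.

    Patient totals are normally taken as given; this helper only converts
    when a laboratory reports concentration (mg/dL) and volume (dL).
    """
    if volume_dl < 0:
        raise ValidationError("urine volume must be non-negative")
    return float(conc_mg_dl) * float(volume_dl)
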