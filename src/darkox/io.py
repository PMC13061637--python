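"""Validated tabular I/O.

All pipeline tables are comma-separated UTF-8 text with a header row.  Each
schema lists required numeric columns; reading validates the header and
every row, collecting per-line error messages so a single corrupt row is
reported with its line number rather than failing opaquely.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TABLE_SCHEMAS", "TableValidationError", "read_table", "write_table"]

#: schema id -> (required numeric columns, required string columns)
TABLE_SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "optode": (("time_s", "o2_umol_l", "temp_c"), ()),
    "raw_optode": (("time_s", "raw", "temp_c"), ()),
    "profile": (("depth_mm", "o2_umol_l"), ()),
    "voltage": (("volts",), ("site",)),
    "taxon": (("rel_abund",), ("sample", "taxon")),
    "calibration": (
        ("temperature_c", "saturation_level", "raw_reading", "reference_o2"),
        (),
    ),
    "winkler": (("syringe_time_h", "titration_1", "titration_2"), ("experiment_id",)),
    "inventory": (
        ("q_g", "ea_ev", "g_per100ev", "a_g_mol", "lambda_per_yr"),
        ("isotope", "compartment"),
    ),
    "flux_results": ((), ()),  # free-form results table, header checked only
}


class TableValidationError(ValueError):
    """Raised when a table fails schema validation; carries per-line errors."""

    def __init__(self, path, errors: list[str]):
        self.errors = errors
        super().__init__(
            f"{path}: {len(errors)} validation error(s):\n  " + "\n  ".join(errors)
        )


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Numeric columns are converted with per-row error collection; line
    numbers refer to the file (header is line 1).
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    numeric_cols, string_cols = TABLE_SCHEMAS[schema]
    errors: list[str] = []
    missing = [c for c in (*numeric_cols, *string_cols) if c not in df.columns]
    if missing:
        raise TableValidationError(path, [f"missing column(s): {', '.join(missing)}"])
    out = {}
    for col in df.columns:
        if col in numeric_cols or col not in string_cols:
            converted = pd.to_numeric(df[col], errors="coerce")
            if col in numeric_cols:
                bad = df.index[converted.isna() & (df[col] != "")]
                for i in bad:
                    errors.append(
                        f"line {i + 2}: column {col!r}: "
                        f"unparseable value {df[col].iloc[i]!r}"
                    )
                empty = df.index[df[col] == ""]
                for i in empty:
                    errors.append(f"line {i + 2}: column {col!r}: empty value")
            out[col] = converted if not converted.isna().all() else df[col]
        else:
            out[col] = df[col]
    if errors:
        raise TableValidationError(path, errors)
    result = pd.DataFrame(out)
    for col in string_cols:
        result[col] = df[col]
    return result


def write_table(df: pd.DataFrame, path) -> None:
    """Write a results table as headered CSV (UTF-8, no index column)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
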