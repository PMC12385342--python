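"""CSV readers/writers for the pipeline's tabular interchange formats.

All tables are plain CSV with exact headers; empty cells denote missing
values.  Floats are written at full precision so that repeated runs with
the same seed produce byte-identical files.
"""

from __future__ import annotations

import pandas as pd

from .estimators import (MEASUREMENT_COLUMNS, VOLUME_COLUMNS,
                         SchemaError, validate_measurements)

_MEASUREMENT_DTYPES = {"dog_id": str, "group": str, "phase": str}


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a measurement CSV (schema error names the
    offending column)."""
    try:
        df = pd.read_csv(path, dtype=_MEASUREMENT_DTYPES)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty measurement file: {path}") from exc
    validate_measurements(df)
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    df[MEASUREMENT_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_volumes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"dog_id": str, "method": str, "phase": str})
    missing = [c for c in VOLUME_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise SchemaError(f"empty volume table: {path}")
    return df


def write_volumes(df: pd.DataFrame, path) -> None:
    df[VOLUME_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def write_table(df: pd.DataFrame, path) -> None:
    """Write an analysis summary table (agreement, reproducibility,
    Bland-Altman points, CI-overlap) as CSV."""
    df.to_csv(path, index=False, float_format="%.12g")
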