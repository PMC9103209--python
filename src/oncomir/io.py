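"""Validated CSV table I/O shared by the CLI and the pipeline.

All tables are UTF-8 CSV with a header row and "." as the decimal
separator.  On input the tokens "", "NA" and "Undetermined" are parsed as
missing values (an undetermined qPCR well is missing data, never a
pseudo-Ct at the detection limit).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["MISSING_TOKENS", "SCHEMAS", "read_table", "write_table"]

MISSING_TOKENS = ["", "NA", "Undetermined"]

#: Required columns per logical table; extra columns are preserved.
SCHEMAS: dict[str, dict] = {
    "ct_long": {
        "required": ["sample_id", "assay", "replicate", "ct"],
        "numeric": ["replicate", "ct"],
    },
    "metadata": {
        "required": ["patient_id", "sample_id", "diagnosis", "group", "compartment"],
        "numeric": [],
    },
    "expression": {"required": ["sample_id"], "numeric": []},
    "scores": {"required": ["sample_id", "score"], "numeric": ["score"]},
    "survival": {
        "required": ["patient_id", "time", "event"],
        "numeric": ["time", "event"],
    },
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises ``ValueError`` naming the file and any missing required
    columns; parse failures carry the offending file name.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    spec = SCHEMAS[schema]
    try:
        df = pd.read_csv(path, na_values=MISSING_TOKENS, keep_default_na=True)
    except Exception as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )
    for col in spec["numeric"]:
        try:
            df[col] = pd.to_numeric(df[col])
        except Exception as exc:
            raise ValueError(f"{path}: column {col!r} is not numeric: {exc}") from exc
    return df


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> Path:
    """Write a CSV (UTF-8, '.' decimals); round-trips through read_table."""
    path = Path(path)
    if schema is not None:
        spec = SCHEMAS[schema]
        missing = [c for c in spec["required"] if c not in df.columns]
        if missing:
            raise ValueError(f"refusing to write {path}: missing columns {missing}")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
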