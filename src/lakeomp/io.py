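"""Validated CSV table I/O with named column schemas."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table"]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


#: required columns (and which must parse as numeric) per schema name
SCHEMAS: dict[str, dict[str, list[str]]] = {
    "feature_table": {
        "required": ["feature_id", "mz", "rt_min"],
        "numeric": ["mz", "rt_min"],
    },
    "concentrations": {
        "required": ["compound", "depth_m", "value_ngL", "censored", "loq_ngL"],
        "numeric": ["depth_m", "value_ngL", "loq_ngL"],
    },
    "site_concentrations": {
        "required": [
            "compound", "site_group", "date", "value_ngL", "censored", "loq_ngL",
        ],
        "numeric": ["value_ngL", "loq_ngL"],
    },
    "temperature": {
        "required": ["date", "depth_m", "temp_c"],
        "numeric": ["depth_m", "temp_c"],
    },
    "hypsograph": {
        "required": ["depth_m", "area_m2"],
        "numeric": ["depth_m", "area_m2"],
    },
    "network": {
        "required": [
            "site", "role", "date", "discharge_m3d", "compound", "conc_ngL",
            "class",
        ],
        "numeric": ["discharge_m3d", "conc_ngL"],
    },
    "acc": {
        "required": ["compound", "endpoint", "acc_uM", "molecular_weight"],
        "numeric": ["acc_uM", "molecular_weight"],
    },
    "metrics": {
        "required": ["compound", "pbias_pct", "nse"],
        "numeric": ["pbias_pct", "nse"],
    },
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a CSV and validate it against a named schema.

    Required columns must be present (a missing one raises
    :class:`SchemaError` naming it); declared numeric columns must
    parse, otherwise a parse error cites the first offending row. Extra
    columns are preserved.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema '{schema}'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    spec = SCHEMAS[schema]
    for col in spec["required"]:
        if col not in frame.columns:
            raise SchemaError(f"{path.name}: missing required column '{col}'")
    for col in spec["numeric"]:
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = parsed.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path.name}: malformed numeric value in column '{col}' "
                f"at row {row}"
            )
        frame[col] = parsed
    return frame


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as CSV (no index), creating parent directories."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path
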