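"""CSV schemas and validation for ratings, schedules and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SCORE_TYPES

__all__ = ["read_ratings", "write_ratings", "read_schedule_csv", "SchemaError"]

_COLUMNS = ["subject_id", "item_id", "score_type", "value"]


class SchemaError(ValueError):
    """A ratings table violated its schema; the message names row and column."""


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    bad_type = ~table["score_type"].isin(SCORE_TYPES)
    if bad_type.any():
        row = int(table.index[bad_type][0])
        raise SchemaError(
            f"row {row}, column score_type: {table.loc[row, 'score_type']!r} "
            f"is not one of {list(SCORE_TYPES)}"
        )
    values = pd.to_numeric(table["value"], errors="coerce")
    bad_val = values.isna() | (values < 0) | (values > 10)
    if bad_val.any():
        row = int(table.index[bad_val][0])
        raise SchemaError(
            f"row {row}, column value: {table.loc[row, 'value']!r} outside [0, 10]"
        )
    dup = table.duplicated(subset=["subject_id", "item_id", "score_type"])
    if dup.any():
        row = int(table.index[dup][0])
        key = tuple(table.loc[row, ["subject_id", "item_id", "score_type"]])
        raise SchemaError(f"row {row}: duplicate (subject, item, score_type) key {key}")
    out = table[_COLUMNS].copy()
    out["value"] = values
    return out


def read_ratings(path) -> pd.DataFrame:
    """Read and validate a long-format ratings CSV."""
    return _validate(pd.read_csv(path))


def write_ratings(table: pd.DataFrame, path) -> None:
    """Validate and write a ratings table, lossless to 10 significant digits."""
    out = _validate(table)
    out.to_csv(path, index=False, float_format="%.10g")


def read_schedule_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    needed = {"item_id", "expected"}
    if not needed.issubset(table.columns):
        raise SchemaError(f"schedule CSV needs columns {sorted(needed)}")
    return table


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(x)}")
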