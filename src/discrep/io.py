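"""Reading effect tables and writing analysis records.

Effect tables are delimited text with header columns ``study``, ``beta``,
``se`` (TSV by default); results are JSON with full-precision numbers and
enough provenance (seed, iterations, statistic) to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .effects import EffectTable

__all__ = ["read_effect_table", "write_result", "read_result", "result_record"]

_SEPARATORS = {"tsv": "\t", "csv": ","}


def read_effect_table(path: str | Path, format: str = "tsv") -> EffectTable:
    """Read and validate a per-study effect table.

    Raises distinct, row-annotated errors for missing columns,
    non-positive or missing standard errors, and tables with fewer than
    two studies.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"effect table not found: {path}")
    try:
        sep = _SEPARATORS[format]
    except KeyError:
        raise ValueError(f"format must be one of {sorted(_SEPARATORS)}, got {format!r}")
    df = pd.read_csv(path, sep=sep)
    missing = {"study", "beta", "se"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            f"found {list(df.columns)}"
        )
    for col in ("beta", "se"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            raise ValueError(f"{path}: non-numeric or missing {col!r} at rows {bad}")
        df[col] = vals
    bad = df.index[df["se"] <= 0].tolist()
    if bad:
        raise ValueError(f"{path}: non-positive standard error at rows {bad}")
    if len(df) < 2:
        raise ValueError(f"{path}: at least 2 studies required, found {len(df)}")
    return EffectTable.from_dataframe(df)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def result_record(result: Any, **extra: Any) -> dict:
    """Flatten a result object into a JSON-serializable dict."""
    record = _jsonable(result)
    if not isinstance(record, dict):
        record = {"value": record}
    record.update(_jsonable(extra))
    return record


def write_result(result: Any, path: str | Path, **extra: Any) -> None:
    """Serialize a result (dataclass or dict) as JSON at full precision."""
    path = Path(path)
    try:
        path.write_text(json.dumps(result_record(result, **extra), indent=2) + "\n")
    except OSError as exc:
        raise OSError(f"could not write result to {path}: {exc}") from exc


def read_result(path: str | Path) -> dict:
    """Read back a JSON result record."""
    return json.loads(Path(path).read_text())
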