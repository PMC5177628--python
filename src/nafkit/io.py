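"""Table and configuration readers/writers.

Two CSV/TSV dialects are supported:

* ``long`` — one row per measurement with columns
  ``sample_id, condition, replicate, fraction_index, analyte_id, kind, value``.
* ``wide`` — one row per (sample, analyte) with columns
  ``sample_id, condition, replicate, analyte_id, kind`` followed by one
  column per fraction named ``f1 .. fN`` (1-based, fraction 1 the lightest).

Empty cells mean "not detected" and are dropped from the long form.
Decimal points are locale-independent; files are UTF-8.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import (
    EXPERIMENT_COLUMNS,
    ExperimentTable,
    SchemaError,
    ValidationError,
)

_META_COLUMNS = ("sample_id", "condition", "replicate", "analyte_id", "kind")


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_experiment(
    path: str | Path,
    dialect: str = "long",
    sep: str | None = None,
    fraction_densities: dict[int, float] | None = None,
) -> ExperimentTable:
    """Read an experiment table from CSV/TSV in either dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    if dialect == "long":
        missing = [c for c in EXPERIMENT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path.name}: missing column(s) {missing}")
        df = df.dropna(subset=["value"])
    elif dialect == "wide":
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path.name}: missing column(s) {missing}")
        frac_cols = [c for c in df.columns if c not in _META_COLUMNS]
        if not frac_cols:
            raise SchemaError(f"{path.name}: no fraction columns (f1..fN)")
        try:
            indices = {c: int(str(c).lstrip("fF")) for c in frac_cols}
        except ValueError as exc:
            raise SchemaError(
                f"{path.name}: fraction columns must be named f1..fN"
            ) from exc
        df = df.melt(
            id_vars=list(_META_COLUMNS),
            value_vars=frac_cols,
            var_name="fraction_column",
            value_name="value",
        )
        df["fraction_index"] = df["fraction_column"].map(indices)
        df = df.drop(columns="fraction_column").dropna(subset=["value"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return ExperimentTable(
        df.reset_index(drop=True), fraction_densities=fraction_densities
    )


def write_experiment(
    table: ExperimentTable,
    path: str | Path,
    dialect: str = "long",
    sep: str | None = None,
) -> None:
    """Write an experiment table in the requested dialect."""
    path = Path(path)
    sep = _sep_for(path, sep)
    if dialect == "long":
        table.data.to_csv(path, sep=sep, index=False)
    elif dialect == "wide":
        wide = table.data.pivot_table(
            index=list(_META_COLUMNS),
            columns="fraction_index",
            values="value",
            dropna=False,
        )
        wide.columns = [f"f{int(c)}" for c in wide.columns]
        wide.reset_index().to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise ValidationError(f"{path.name}: config must be a mapping")
    return loaded


def dump_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
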