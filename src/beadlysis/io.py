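"""Plain-text readers/writers and provenance for the pipeline.

Everything on disk is CSV, JSON or YAML.  Every run of a pipeline stage
writes a provenance block (parameter echo, seed, package version) next to
its outputs so results can be regenerated exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .outcomes import RECORD_COLUMNS, validate_records

__all__ = [
    "read_records",
    "write_records",
    "write_json",
    "read_params",
    "write_provenance",
]

_BOOL_COLS = ("cleaved", "bundled", "elongated")


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def write_records(records, path) -> None:
    """Write fiber fate records to CSV with the fixed header."""
    df = validate_records(records)
    df.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    """Read and validate a fiber fate record CSV."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record CSV missing columns: {missing}")
    for c in _BOOL_COLS:
        if df[c].dtype == object:
            df[c] = df[c].map({"True": True, "False": False, True: True, False: False})
        df[c] = df[c].astype(bool)
    df["trial_id"] = df["trial_id"].astype(str)
    return validate_records(df)


def read_params(path) -> dict:
    """Read a YAML/JSON parameter file into a flat dict."""
    text = Path(path).read_text()
    return yaml.safe_load(text) or {}


def write_provenance(out_path, stage: str, params: dict, seed=None) -> Path:
    """Write ``<out>.provenance.json`` echoing the run configuration."""
    from . import __version__

    prov = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "params": _jsonable(params),
    }
    p = Path(str(out_path) + ".provenance.json")
    p.write_text(json.dumps(prov, indent=2) + "\n")
    return p
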