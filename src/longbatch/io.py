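"""TSV/JSON readers and writers.

All interchange is tab-separated text (human-diffable); paths ending in
``.gz`` are transparently compressed.  Expression round-trips losslessly at
full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import validate_expression, validate_meta, validate_probes

__all__ = [
    "read_expression", "write_expression",
    "read_meta", "write_meta",
    "read_probes", "write_probes",
    "write_json", "read_json",
]


def _check_header_unique(path) -> None:
    # pandas silently mangles duplicate column names, so inspect the header
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dupes = sorted({name for name in header if name in seen or seen.add(name)})
    if dupes:
        raise ValueError(f"{path}: duplicate sample IDs {dupes}")


def read_expression(path) -> pd.DataFrame:
    """Read a probes x samples TSV (probe-ID first column, sample-ID header)."""
    _check_header_unique(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as err:
        raise ValueError(f"{path}: non-numeric expression cell ({err})") from err
    if df.isna().any().any():
        bad = df.isna().stack()
        probe, sample = bad.index[bad.to_numpy().nonzero()[0][0]]
        raise ValueError(f"{path}: missing value at probe {probe!r}, "
                         f"sample {sample!r} (ragged row?)")
    return validate_expression(df.astype(float))


def write_expression(expr: pd.DataFrame, path) -> None:
    validate_expression(expr)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # repr-precision floats: read(write(x)) == x exactly
    expr.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def read_meta(path, expr: pd.DataFrame | None = None) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    return validate_meta(meta, expr)


def write_meta(meta: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta.to_csv(path, sep="\t")


def read_probes(path, expr: pd.DataFrame | None = None) -> pd.DataFrame:
    probes = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("is_negative_control", "on_version3", "on_version4"):
        if col in probes.columns:
            probes[col] = probes[col].astype(bool)
    return validate_probes(probes, expr)


def write_probes(probes: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    probes.to_csv(path, sep="\t")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, default=str)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
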