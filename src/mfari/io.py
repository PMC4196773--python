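"""Delimited-text I/O for manoeuvre time series and analysis reports.

Time-series files are CSV with a header row and columns ``time, abp, cbfv``
(names configurable); decimal points, never decimal commas. Metadata (cuff
release time ``t0``, subject and repetition labels) travels either in a
sidecar YAML/JSON file with the same stem or is supplied explicitly — there
is no silent default for ``t0``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError
from .preprocess import Manoeuvre

__all__ = [
    "read_manoeuvre",
    "write_manoeuvre",
    "read_sidecar",
    "read_reliability_tidy",
]


def read_sidecar(path: Path) -> dict:
    """Metadata from ``<stem>.yaml``/``.yml``/``.json`` next to a data file."""
    path = Path(path)
    for ext in (".yaml", ".yml", ".json"):
        side = path.with_suffix(ext)
        if side.exists():
            with open(side) as fh:
                if ext == ".json":
                    return json.load(fh)
                return yaml.safe_load(fh)
    return {}


def read_manoeuvre(
    path,
    t0: float | None = None,
    rate: float | None = None,
    time_col: str = "time",
    abp_col: str = "abp",
    cbfv_col: str = "cbfv",
) -> Manoeuvre:
    """Load a uniformly sampled manoeuvre from CSV plus sidecar metadata.

    ``t0`` (and optionally ``rate``) may come from the sidecar; an explicit
    argument wins. Raises a descriptive error naming the missing column or
    metadata field.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in (time_col, abp_col, cbfv_col):
        if col not in df.columns:
            raise InvalidParameterError(
                f"{path.name}: missing column {col!r} (have {list(df.columns)})"
            )
    meta = read_sidecar(path)
    if t0 is None:
        t0 = meta.get("t0")
    if t0 is None:
        raise InvalidParameterError(
            f"{path.name}: cuff-release time t0 not given and no sidecar provides it"
        )
    time = df[time_col].to_numpy(dtype=float)
    if rate is None:
        steps = np.diff(time)
        if steps.size == 0 or not np.allclose(steps, steps[0], rtol=1e-6):
            raise InvalidParameterError(
                f"{path.name}: time column is not uniformly sampled; pass rate"
            )
        rate = 1.0 / steps[0]
    keep = {
        k: v for k, v in meta.items() if k not in ("t0", "rate")
    }
    return Manoeuvre(
        abp=df[abp_col].to_numpy(dtype=float),
        cbfv=df[cbfv_col].to_numpy(dtype=float),
        rate=float(rate),
        t0=float(t0) - float(time[0]),
        meta=keep,
    )


def write_manoeuvre(m: Manoeuvre, path, sidecar: bool = True) -> None:
    """Write a manoeuvre to CSV (columns time, abp, cbfv) plus a YAML sidecar."""
    path = Path(path)
    pd.DataFrame({"time": m.time, "abp": m.abp, "cbfv": m.cbfv}).to_csv(
        path, index=False
    )
    if sidecar:
        meta = {"t0": float(m.t0), "rate": float(m.rate)}
        for k, v in m.meta.items():
            if isinstance(v, (str, int, float, bool)):
                meta[k] = v
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)


def read_reliability_tidy(path) -> pd.DataFrame:
    """Tidy (subject, repetition, index, value) table from CSV."""
    df = pd.read_csv(path)
    required = {"subject", "repetition", "value"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(
            f"{Path(path).name}: missing columns {sorted(missing)}"
        )
    return df
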