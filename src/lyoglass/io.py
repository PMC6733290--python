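"""Plain-text column files shared by every modality.

Dialect: tab-separated numeric columns with a header of ``#``-prefixed
``key: value`` metadata lines followed by one ``#``-prefixed line of column
names.  The same dialect is produced by the synthetic generator and read by
every analysis stage, so user-supplied instrument exports only need to match
this minimal layout.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def write_columns(
    path: str | Path,
    columns: Mapping[str, np.ndarray],
    meta: Mapping[str, object] | None = None,
) -> None:
    names = list(columns)
    arrays = [np.asarray(columns[n], dtype=float) for n in names]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all columns must have equal length")
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("# " + "\t".join(names) + "\n")
        for row in zip(*arrays):
            fh.write("\t".join(format(v, ".12g") for v in row) + "\n")


def _coerce(value: str) -> object:
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def read_columns(path: str | Path) -> tuple[pd.DataFrame, dict[str, object]]:
    """Read a column file, returning the data frame and parsed metadata."""
    meta: dict[str, object] = {}
    names: Sequence[str] | None = None
    with open(path) as fh:
        lines = fh.readlines()
    data_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            data_start = i
            break
        body = line[1:].strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = _coerce(value.strip())
        elif body:
            names = body.split("\t") if "\t" in body else body.split()
    else:  # file was all comments
        data_start = len(lines)
    rows = [ln.split() for ln in lines[data_start:] if ln.strip()]
    if not rows:
        raise ValueError(f"no data rows in {path}")
    values = np.asarray(rows, dtype=float)
    if names is None or len(names) != values.shape[1]:
        names = [f"col{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, columns=list(names)), meta
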