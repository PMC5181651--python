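"""Delimited-table I/O for composition matrices and result tables.

Composition tables are plain CSV: a header row of part labels, one
observation per row, optionally preceded by a non-numeric id column (auto
detected and kept as the row index).  Result tables are written with
``#``-prefixed metadata comment lines (seed, package version, estimator
settings) that are skipped on re-read, so the same file is both
human-auditable and machine-round-trippable.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import validate_composition_matrix

__all__ = ["TableDialect", "read_composition_table",
           "write_composition_table", "write_result_table"]


@dataclass
class TableDialect:
    delimiter: str = ","
    header: bool = True
    id_column: bool | None = None     # None = auto-detect

    def __post_init__(self):
        if len(self.delimiter) != 1:
            raise ValueError("delimiter must be a single character")


def read_composition_table(path, dialect: TableDialect | None = None) -> pd.DataFrame:
    """Read and validate a composition matrix from a delimited text file.

    A first column of non-numeric content is treated as observation ids and
    becomes the index.  Any non-positive or missing cell raises with the
    offending row and column named.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep=dialect.delimiter, comment="#",
                     header=0 if dialect.header else None,
                     float_precision="round_trip")
    if not dialect.header:
        df.columns = [f"part_{j + 1}" for j in range(df.shape[1])]
    use_id = dialect.id_column
    if use_id is None:
        first = df.iloc[:, 0]
        use_id = not pd.api.types.is_numeric_dtype(first)
    if use_id:
        df = df.set_index(df.columns[0])
    return validate_composition_matrix(df)


def write_composition_table(X, path, dialect: TableDialect | None = None) -> None:
    """Write a composition matrix losslessly (17 significant digits)."""
    dialect = dialect or TableDialect()
    X = validate_composition_matrix(X)
    X.to_csv(path, sep=dialect.delimiter, float_format="%.17g",
             index=bool(X.index.name), lineterminator="\n")


def write_result_table(result, path, metadata: dict | None = None) -> None:
    """Write a tidy result table (or report dict) as CSV with '#' metadata.

    Two writes of the same result are byte-identical; metadata lines record
    seed and estimator settings and are skipped by
    :func:`read_composition_table` and ``pd.read_csv(..., comment='#')``.
    """
    from . import __version__
    from .metrics import DistortionReport

    if isinstance(result, DistortionReport):
        result = pd.DataFrame([result.as_dict()])
    if not isinstance(result, pd.DataFrame):
        raise TypeError(f"cannot write result of type {type(result).__name__}")
    buf = _io.StringIO()
    buf.write(f"# codaprop {__version__}\n")
    for key in sorted(metadata or {}):
        buf.write(f"# {key}: {json.dumps(_jsonable(metadata[key]))}\n")
    result.to_csv(buf, index=False, lineterminator="\n")
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v
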