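"""Flat-file formats: headered TSV matrices, GMT gene sets, config echo.

All tabular artifacts are UTF-8 tab-separated files with a header row and the
literal ``NA`` for missing values.  Lines starting with ``#`` are metadata
comments (tool version, config hash, seed) and are skipped on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_table_tsv",
    "write_table_tsv",
    "read_gmt",
    "write_gmt",
    "config_hash",
    "header_comment",
]


class FormatError(ValueError):
    pass


def _read_rows(path: str | Path) -> tuple[list[list[str]], list[int]]:
    rows, linenos = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
            linenos.append(lineno)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return rows, linenos


def read_matrix_tsv(path: str | Path, orientation: str = "rows") -> pd.DataFrame:
    """Read a numeric matrix with row/column ids; ``NA`` encodes missing.

    ``orientation='rows'`` keeps the file layout; ``'columns'`` transposes.
    Ragged rows and duplicate ids are hard errors naming the offending line.
    """
    rows, linenos = _read_rows(path)
    header = rows[0]
    width = len(header)
    data, ids = [], []
    for row, lineno in zip(rows[1:], linenos[1:]):
        if len(row) != width:
            raise FormatError(f"{path}: ragged row at line {lineno} "
                              f"({len(row)} fields, expected {width})")
        ids.append(row[0])
        data.append([np.nan if v == "NA" else float(v) for v in row[1:]])
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate row ids {dup[:5]}")
    cols = header[1:]
    if len(set(cols)) != len(cols):
        raise FormatError(f"{path}: duplicate column ids")
    df = pd.DataFrame(data, index=pd.Index(ids, name=header[0]), columns=cols, dtype=float)
    if orientation == "columns":
        df = df.T
    elif orientation != "rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return df


def write_matrix_tsv(path: str | Path, df: pd.DataFrame, comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", lineterminator="\n")


def read_table_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """General typed table (mixed string/numeric columns)."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], keep_default_na=False,
                     index_col=index_col)
    return df


def write_table_tsv(path: str | Path, df: pd.DataFrame, comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", lineterminator="\n")


def read_gmt(path: str | Path) -> list[dict]:
    """Parse a GMT file: one gene set per line (name, description, genes...).

    Duplicate genes within a set are removed (first occurrence wins) with a
    warning; lines with fewer than three fields are errors.
    """
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: GMT line {lineno} has {len(fields)} fields (need >= 3)")
            genes, seen = [], set()
            for g in fields[2:]:
                if g in seen:
                    logger.warning("read_gmt: duplicate gene %r in set %r (line %d)", g, fields[0], lineno)
                    continue
                seen.add(g)
                genes.append(g)
            sets.append({"name": fields[0], "description": fields[1], "genes": genes})
    return sets


def write_gmt(path: str | Path, sets: list[dict]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s["name"], s["description"], *map(str, s["genes"])]) + "\n")


def config_hash(obj) -> str:
    """Stable short hash of a (nested) config mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def header_comment(version: str, cfg_hash: str, seed: int) -> str:
    return f"musclemap v{version} config={cfg_hash} seed={seed}"
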