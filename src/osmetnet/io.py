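"""Shared readers and writers for the tabular formats the pipeline exchanges.

All tables are plain TSV with a header row. Gene-set collections use the
standard GMT layout (set name, description, then a variable number of member
genes, tab-separated).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd


class SchemaError(ValueError):
    """A table does not match its declared column schema."""


def read_table(path: str | Path, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a TSV table, optionally validating that ``columns`` are present.

    Raises :class:`SchemaError` naming the missing columns when validation
    fails, so pipeline stages can abort with an actionable message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path}: expected columns {list(columns)}, missing {missing} "
                f"(found {list(df.columns)})"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a TSV table with header, no index. Returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample expression TSV (first column ``gene``).

    Returns a DataFrame indexed by gene symbol with one column per sample.
    """
    df = read_table(path, columns=["gene"])
    df = df.set_index("gene")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicated gene ids in expression matrix: {dups[:5]}")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> Path:
    out = expr.reset_index()
    out.columns = ["gene"] + list(expr.columns)
    return write_table(out, path)


def read_groups(path: str | Path) -> pd.Series:
    """Read a sample→group TSV (columns ``sample``, ``group``)."""
    df = read_table(path, columns=["sample", "group"])
    bad = set(df["group"]) - {"case", "control"}
    if bad:
        raise SchemaError(f"unknown group labels {sorted(bad)}; expected case/control")
    return df.set_index("sample")["group"]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into ``{set name: member genes}``.

    Rows shorter than three fields (name, description, ≥1 gene) are rejected.
    """
    collection: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise SchemaError(f"{path}:{lineno}: GMT row needs name, description, members")
        name = fields[0]
        if name in collection:
            raise SchemaError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        members = {g for g in fields[2:] if g}
        if not members:
            raise SchemaError(f"{path}:{lineno}: gene set {name!r} has no members")
        collection[name] = members
    return collection


def write_gmt(collection: Mapping[str, set[str]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, "na"] + sorted(members)) + "\n")
    return path


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-column gene list (header optional, ``gene`` if present)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].lower() == "gene":
        lines = lines[1:]
    return set(lines)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path
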