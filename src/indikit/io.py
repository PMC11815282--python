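"""File-format plumbing: long/wide expression tables, GMT gene sets, JSON.

Values are read as given — no normalisation or log transformation happens
here; the unit string is a display label only. Delimiters are inferred from
the extension (``.tsv``/``.txt``/``.gmt`` tab, otherwise comma) and can be
overridden. Round-tripping a canonical table through ``write_table`` /
``read_expression`` is the identity.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .harmonize import validate_gene_sets

_TAB_EXTENSIONS = {".tsv", ".txt", ".gmt"}


def _sep_for(path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if Path(path).suffix.lower() in _TAB_EXTENSIONS else ","


def read_expression(path, sep: str | None = None) -> pd.DataFrame:
    """Read a long-format expression table (CSV/TSV by extension)."""
    try:
        df = pd.read_csv(path, sep=_sep_for(path, sep))
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValidationError(f"malformed table {path}: {exc}") from exc
    if df.empty:
        raise ValidationError(f"empty table: {path}")
    return df


def read_wide_matrix(matrix_path, metadata_path, sep: str | None = None) -> pd.DataFrame:
    """Read a genes x samples matrix plus per-sample metadata; melt to long.

    The matrix's first column holds feature names and the remaining column
    headers are sample ids; the metadata table must have a ``sample_id``
    column and one row per sample. Metadata columns are joined onto the
    melted records.
    """
    mat = pd.read_csv(matrix_path, sep=_sep_for(matrix_path, sep), index_col=0)
    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path, sep))
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata must contain a 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("metadata has duplicated sample_id rows")
    long = (
        mat.reset_index(names="feature")
        .melt(id_vars="feature", var_name="sample_id", value_name="value")
    )
    missing = set(long["sample_id"]) - set(meta["sample_id"].astype(str))
    if missing:
        raise ValidationError(
            f"samples in matrix without metadata: {sorted(missing)[:10]}"
        )
    return long.merge(meta, on="sample_id", how="left")


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, _desc, *members = parts
            members = [m for m in members if m]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    validate_gene_sets(sets)
    return sets


def read_gene_sets_json(path) -> dict[str, list[str]]:
    """Read gene sets from a JSON mapping ``{name: [genes]}``."""
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or not all(isinstance(v, list) for v in doc.values()):
        raise ValidationError("gene-set JSON must map names to lists of genes")
    sets = {str(k): [str(g) for g in v] for k, v in doc.items()}
    validate_gene_sets(sets)
    return sets


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read gene sets, dispatching on extension (.gmt vs .json)."""
    if Path(path).suffix.lower() == ".gmt":
        return read_gmt(path)
    return read_gene_sets_json(path)


def write_table(tbl: pd.DataFrame, path, sep: str | None = None) -> None:
    """Write a table as CSV/TSV chosen by extension."""
    tbl.to_csv(path, sep=_sep_for(path, sep), index=False)


def write_json(doc: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
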