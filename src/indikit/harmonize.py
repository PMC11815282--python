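"""Canonical long-format expression tables and pathway-level aggregation.

Every operation in this package consumes a *harmonized table*: a pandas
DataFrame in long format with one row per (sample, feature) measurement and
the canonical columns

``patient_id``
    opaque patient identifier; links paired samples.
``sample_id``
    opaque sample identifier; unique per (sample, feature) pair.
``feature``
    gene symbol or pathway/signature name.
``value``
    expression on the log2 scale (e.g. log2 TPM). Values are taken as given;
    no normalisation or re-logging is ever applied.
``unit``
    a single display label (used in figure captions), identical on all rows.

plus zero or more named categorical *group columns* (indication, treatment,
database, ...). An optional combined column ``"intr"`` concatenates selected
group columns with ``"_"`` for display/grouping; it is never re-parsed.

Gene sets are plain mappings ``{set_name: [gene, ...]}`` with unique names
and non-empty member lists; :func:`aggregate_gene_sets` collapses them to
per-sample mean log2 expression ("pathway scores").
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Columns every harmonized table must carry.
CANONICAL_COLUMNS = ("patient_id", "sample_id", "feature", "value", "unit")

#: Name of the combined grouping column.
INTR_COLUMN = "intr"

#: Join character for the combined grouping column.
INTR_JOIN = "_"


def validate_table(tbl: pd.DataFrame, group_cols: Sequence[str] = ()) -> None:
    """Check the harmonized-table invariants, raising ``ValidationError``.

    Checks: canonical columns present; no missing patient/sample/feature;
    (sample_id, feature) unique; a single unit label; no empty-string
    categories in ``group_cols``.
    """
    missing = [c for c in CANONICAL_COLUMNS if c not in tbl.columns]
    if missing:
        raise ValidationError(f"missing canonical column(s): {missing}")
    for col in ("patient_id", "sample_id", "feature"):
        if tbl[col].isna().any():
            n = int(tbl[col].isna().sum())
            raise ValidationError(f"{n} record(s) with missing {col}")
    dup = tbl.duplicated(subset=["sample_id", "feature"])
    if dup.any():
        offenders = (
            tbl.loc[dup, ["sample_id", "feature"]].head(5).to_records(index=False)
        )
        raise ValidationError(
            f"duplicated (sample_id, feature) pairs; first offenders: {list(offenders)}"
        )
    units = tbl["unit"].dropna().unique()
    if len(units) > 1:
        raise ValidationError(f"more than one unit label: {sorted(map(str, units))}")
    for col in group_cols:
        if col not in tbl.columns:
            raise ValidationError(f"group column {col!r} not in table")
        if (tbl[col].astype(str) == "").any():
            raise ValidationError(f"group column {col!r} contains empty-string categories")


def harmonize_table(
    raw: pd.DataFrame,
    column_map: Mapping[str, str],
    keep_groups: Sequence[str] = (),
    combine_groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rename, subset, and validate a raw long-format table.

    Parameters
    ----------
    raw
        Long-format records, one row per (sample, feature) measurement.
    column_map
        Mapping raw column name -> canonical column name. Must cover
        ``patient_id``, ``sample_id``, ``feature`` and ``value``; may cover
        ``unit`` and group columns. Unmapped raw columns are dropped unless
        listed (post-rename) in ``keep_groups``.
    keep_groups
        Group columns (canonical names) to retain.
    combine_groups
        If given, these group columns are concatenated with ``"_"`` into a
        combined ``"intr"`` column for display/grouping.

    Records with a missing expression value are dropped (logged); rows are
    otherwise passed through unchanged, so harmonizing an already-canonical
    table with an identity map is the identity.
    """
    needed = {"patient_id", "sample_id", "feature", "value"}
    mapped_to = set(column_map.values())
    if not needed <= mapped_to:
        raise ValidationError(
            f"column_map must cover {sorted(needed - mapped_to)}"
        )
    absent = [c for c in column_map if c not in raw.columns]
    if absent:
        raise ValidationError(f"mapped column(s) absent from input: {absent}")

    tbl = raw.rename(columns=dict(column_map))
    keep = list(CANONICAL_COLUMNS) + [c for c in keep_groups if c not in CANONICAL_COLUMNS]
    missing_groups = [c for c in keep_groups if c not in tbl.columns]
    if missing_groups:
        raise ValidationError(f"keep_groups column(s) absent: {missing_groups}")
    if "unit" not in tbl.columns:
        tbl["unit"] = "expression"
    tbl = tbl.loc[:, [c for c in keep if c in tbl.columns]].copy()

    n_missing = int(tbl["value"].isna().sum())
    if n_missing:
        logger.warning("dropping %d record(s) with missing expression value", n_missing)
        tbl = tbl.dropna(subset=["value"])
    tbl = tbl.reset_index(drop=True)

    if combine_groups:
        bad = [c for c in combine_groups if c not in tbl.columns]
        if bad:
            raise ValidationError(f"combine_groups column(s) absent: {bad}")
        tbl[INTR_COLUMN] = (
            tbl[list(combine_groups)].astype(str).agg(INTR_JOIN.join, axis=1)
        )
    validate_table(tbl, group_cols=list(keep_groups))
    return tbl


def validate_gene_sets(sets: Mapping[str, Sequence[str]]) -> None:
    """Check that a gene-set collection has unique names and no empty set."""
    if len(set(sets)) != len(sets):
        raise ValidationError("gene set names are not unique")
    for name, members in sets.items():
        if len(members) == 0:
            raise ValidationError(f"gene set {name!r} is empty")


def aggregate_gene_sets(
    tbl: pd.DataFrame,
    sets: Mapping[str, Sequence[str]],
    agg: str = "mean",
    strict: bool = False,
) -> pd.DataFrame:
    """Collapse gene-level rows to pathway-level scores.

    For each set S the per-sample score is the arithmetic mean of that
    sample's log2 values over the genes in S (mean on the log2 scale; no
    de-logging). All sample metadata columns are carried through unchanged.

    Missing-member policy: members absent from the table are dropped with a
    warning (``strict=False``, the default) or raise (``strict=True``); a set
    whose members are all absent always raises.
    """
    if agg != "mean":
        raise ValidationError(f"unsupported aggregation {agg!r}; only 'mean'")
    validate_gene_sets(sets)
    present = set(tbl["feature"].unique())
    meta_cols = [c for c in tbl.columns if c not in ("feature", "value")]

    pieces: list[pd.DataFrame] = []
    for name, members in sets.items():
        members = list(dict.fromkeys(members))  # de-dup, keep order
        found = [m for m in members if m in present]
        missing = [m for m in members if m not in present]
        if not found:
            raise ValidationError(f"gene set {name!r}: no member present in table")
        if missing:
            if strict:
                raise ValidationError(f"gene set {name!r}: missing member(s) {missing}")
            logger.warning("gene set %r: dropping absent member(s) %s", name, missing)
        sub = tbl[tbl["feature"].isin(found)]
        # mean over the set's genes, per sample; metadata is constant per sample
        score = (
            sub.groupby("sample_id", sort=False)["value"].mean().rename("value")
        )
        meta = sub.drop_duplicates("sample_id").set_index("sample_id")[
            [c for c in meta_cols if c != "sample_id"]
        ]
        out = meta.join(score).reset_index()
        out["feature"] = name
        pieces.append(out)

    result = pd.concat(pieces, ignore_index=True)
    cols = ["patient_id", "sample_id", "feature", "value", "unit"] + [
        c for c in result.columns
        if c not in ("patient_id", "sample_id", "feature", "value", "unit")
    ]
    return result.loc[:, cols]
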