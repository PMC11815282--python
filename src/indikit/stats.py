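"""Statistics behind every annotated figure.

All numeric results the figure family prints are computed here: per-gene
global thresholds, percent of samples above threshold, quadrant
classification of two-feature scatter data, composite quadrant-percentage
matrices, fold change and Kruskal-Wallis group comparisons, quartile bins
and hierarchical cluster ordering. Figures never recompute a number.

Conventions, applied uniformly:

* "Above threshold" means **strictly greater**; values on the boundary fall
  to the low side.
* Quadrants follow the flow-cytometry convention: Q2 is high/high
  (upper-right), Q1 upper-left, Q3 lower-left, Q4 lower-right.
* Thresholds are computed over the COMPLETE table, never a displayed subset.
* Fold change on log2-scale inputs is ``2 ** (median(level) - median(ref))``,
  reported on the linear scale.
* No multiple-testing correction anywhere; raw p-values only.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as spd
import scipy.stats as sps

from .errors import ValidationError

SCHEMA_VERSION = "1.0"

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")

ThresholdMethod = Literal["mean", "median", "q3"]
CorrMethod = Literal["spearman", "pearson"]


# ---------------------------------------------------------------------------
# thresholds


@dataclass(frozen=True)
class ThresholdSet:
    """Per-feature global cut-offs.

    ``method`` is one of ``mean`` / ``median`` / ``q3`` (75% quantile, linear
    interpolation between order statistics); ``values`` maps feature ->
    threshold on the expression scale; ``n`` records the sample universe
    (record count per feature) the threshold was computed on.
    """

    method: str
    values: Mapping[str, float]
    n: Mapping[str, int]

    def __getitem__(self, feature: str) -> float:
        try:
            return self.values[feature]
        except KeyError:
            raise ValidationError(f"no threshold for feature {feature!r}") from None

    def to_json(self, path=None) -> str:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "type": "ThresholdSet",
            "method": self.method,
            "values": dict(self.values),
            "n": {k: int(v) for k, v in self.n.items()},
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ThresholdSet":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                doc = json.loads(text)
            else:
                with open(text) as fh:
                    doc = json.load(fh)
        if doc.get("type") != "ThresholdSet":
            raise ValidationError("not a ThresholdSet JSON document")
        return cls(method=doc["method"], values=doc["values"], n=doc["n"])


def compute_thresholds(
    tbl: pd.DataFrame,
    features: Sequence[str] | None = None,
    method: ThresholdMethod = "median",
) -> ThresholdSet:
    """Global per-feature thresholds over ALL samples in ``tbl``.

    Thresholds are always computed on the complete table, even when a later
    plot displays only a subset of groups: comparisons across subsets stay
    anchored to one global cut-off.
    """
    if method not in ("mean", "median", "q3"):
        raise ValidationError(f"unknown threshold method {method!r}")
    if features is None:
        features = list(pd.unique(tbl["feature"]))
    values: dict[str, float] = {}
    counts: dict[str, int] = {}
    grouped = tbl.groupby("feature")["value"]
    for f in features:
        try:
            vals = grouped.get_group(f).to_numpy(dtype=float)
        except KeyError:
            raise ValidationError(f"unknown feature {f!r}") from None
        if vals.size == 0:
            raise ValidationError(f"feature {f!r} has no values")
        if method == "mean":
            thr = float(np.mean(vals))
        elif method == "median":
            thr = float(np.median(vals))
        else:  # q3, linear interpolation
            thr = float(np.quantile(vals, 0.75))
        values[f] = thr
        counts[f] = int(vals.size)
    return ThresholdSet(method=method, values=values, n=counts)


# ---------------------------------------------------------------------------
# percent above / category flags


def _feature_slice(tbl: pd.DataFrame, feature: str) -> pd.DataFrame:
    sub = tbl[tbl["feature"] == feature]
    if sub.empty:
        raise ValidationError(f"unknown feature {feature!r}")
    return sub


def percent_above(
    tbl: pd.DataFrame,
    feature: str,
    threshold: float,
    group_cols: Sequence[str],
) -> pd.DataFrame:
    """Per-group sample count and percent strictly above ``threshold``.

    Returns a tidy frame with the group columns plus ``n`` and ``percent``
    (0-100). Empty groups simply do not appear.
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    sub = _feature_slice(tbl, feature)
    gb = sub.groupby(list(group_cols), sort=True, observed=True)["value"]
    out = gb.agg(
        n="size", percent=lambda v: 100.0 * float((v > threshold).sum()) / len(v)
    ).reset_index()
    return out


def flag_categories_of_interest(
    tbl: pd.DataFrame,
    feature: str,
    threshold: float,
    group_cols: Sequence[str],
) -> pd.DataFrame:
    """Dichotomize categories: group median strictly above the global cut-off.

    A category (e.g. an indication) is "of interest" for the candidate
    therapeutic when its median expression exceeds the global threshold.
    Returns group columns plus ``n``, ``median`` and boolean ``of_interest``.
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    sub = _feature_slice(tbl, feature)
    gb = sub.groupby(list(group_cols), sort=True, observed=True)["value"]
    out = gb.agg(n="size", median="median").reset_index()
    out["of_interest"] = out["median"] > threshold
    return out


# ---------------------------------------------------------------------------
# quadrants


def classify_quadrant(x: float, y: float, thr_x: float, thr_y: float) -> str:
    """Flow-cytometry quadrant of one point.

    Q2: x>thr_x and y>thr_y (high/high, upper-right); Q1 upper-left;
    Q3 lower-left; Q4 lower-right. Boundaries fall to the low side.
    """
    if not all(map(math.isfinite, (x, y, thr_x, thr_y))):
        raise ValidationError("classify_quadrant requires finite inputs")
    hx, hy = x > thr_x, y > thr_y
    if hx and hy:
        return "Q2"
    if hy:
        return "Q1"
    if hx:
        return "Q4"
    return "Q3"


def _classify_quadrants(x: np.ndarray, y: np.ndarray, thr_x: float, thr_y: float) -> np.ndarray:
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite expression values in quadrant classification")
    hx, hy = x > thr_x, y > thr_y
    out = np.where(hx & hy, "Q2", np.where(hy, "Q1", np.where(hx, "Q4", "Q3")))
    return out


@lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    """All n! index permutations as an (n!, n) int8 array (n < 10)."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _corr_with_pvalue(x: np.ndarray, y: np.ndarray, method: CorrMethod) -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value.

    Spearman uses average ranks for ties. p-values: t-approximation for
    n >= 10, exact permutation enumeration for 3 <= n < 10 (every pairing of
    y against x is evaluated). Returns (nan, nan) when n < 3 or a vector is
    constant.
    """
    n = len(x)
    if n < 3:
        return (float("nan"), float("nan"))
    if method == "spearman":
        vx = sps.rankdata(x)
        vy = sps.rankdata(y)
    elif method == "pearson":
        vx = np.asarray(x, dtype=float)
        vy = np.asarray(y, dtype=float)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    sx, sy = vx.std(), vy.std()
    if sx == 0 or sy == 0:
        return (float("nan"), float("nan"))
    r = float(np.corrcoef(vx, vy)[0, 1])
    if n >= 10:
        if abs(r) >= 1.0:
            return (r, 0.0)
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
        return (r, float(min(p, 1.0)))
    # exact permutation null: correlation of vx against every ordering of vy
    perms = _all_permutations(n)
    Y = vy[perms]
    xc = vx - vx.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((Yc**2).sum(axis=1)) * math.sqrt((xc**2).sum())
    r_null = (Yc @ xc) / denom
    p = float(np.mean(np.abs(r_null) >= abs(r) - 1e-12))
    return (r, p)


@dataclass(frozen=True)
class QuadrantResult:
    """Per-group quadrant composition of a two-feature scatter.

    ``table`` holds one row per group: the group columns, ``n``, counts
    ``n_Q1..n_Q4``, percentages ``pct_Q1..pct_Q4`` (summing to 100), and the
    per-group correlation ``corr`` / ``pvalue`` (NaN when fewer than 3 pairs).
    """

    feature_x: str
    feature_y: str
    threshold_x: float
    threshold_y: float
    corr_method: str
    group_cols: tuple[str, ...]
    table: pd.DataFrame

    def to_csv(self, path=None):
        return self.table.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "type": "QuadrantResult",
            "feature_x": self.feature_x,
            "feature_y": self.feature_y,
            "threshold_x": self.threshold_x,
            "threshold_y": self.threshold_y,
            "corr_method": self.corr_method,
            "group_cols": list(self.group_cols),
            "rows": json.loads(self.table.to_json(orient="records")),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def quadrant_stats(
    tbl: pd.DataFrame,
    feature_x: str,
    feature_y: str,
    thresholds: ThresholdSet,
    group_cols: Sequence[str],
    corr: CorrMethod = "spearman",
) -> QuadrantResult:
    """Quadrant counts/percentages and correlation per group.

    The two features are inner-joined on ``sample_id``; each paired sample is
    classified by :func:`classify_quadrant` against the global thresholds, and
    the chosen correlation (with its two-sided p-value) is computed per group
    on the paired values. Groups with fewer than 3 pairs still report counts;
    their correlation is NaN.
    """
    thr_x, thr_y = thresholds[feature_x], thresholds[feature_y]
    wide = pair_features(tbl, feature_x, feature_y, group_cols)
    quad = _classify_quadrants(
        wide["value_x"].to_numpy(), wide["value_y"].to_numpy(), thr_x, thr_y
    )
    wide = wide.assign(quadrant=quad)

    rows = []
    for key, sub in wide.groupby(list(group_cols), sort=True, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        n = len(sub)
        counts = {q: int((sub["quadrant"] == q).sum()) for q in QUADRANTS}
        r, p = _corr_with_pvalue(
            sub["value_x"].to_numpy(), sub["value_y"].to_numpy(), corr
        )
        row = dict(zip(group_cols, key))
        row["n"] = n
        for q in QUADRANTS:
            row[f"n_{q}"] = counts[q]
        for q in QUADRANTS:
            row[f"pct_{q}"] = 100.0 * counts[q] / n
        row["corr"] = r
        row["pvalue"] = p
        rows.append(row)
    table = pd.DataFrame(rows)
    # invariants, cheap enough to assert on every call
    assert ((table[[f"n_{q}" for q in QUADRANTS]].sum(axis=1)) == table["n"]).all()
    assert np.allclose(table[[f"pct_{q}" for q in QUADRANTS]].sum(axis=1), 100.0, atol=1e-9)
    return QuadrantResult(
        feature_x=feature_x,
        feature_y=feature_y,
        threshold_x=thr_x,
        threshold_y=thr_y,
        corr_method=corr,
        group_cols=tuple(group_cols),
        table=table,
    )


def pair_features(
    tbl: pd.DataFrame,
    feature_x: str,
    feature_y: str,
    group_cols: Sequence[str],
) -> pd.DataFrame:
    """Inner-join two features on sample_id into one wide frame.

    Columns: sample_id, patient_id, group columns, value_x, value_y. Group
    metadata is taken from the x-feature rows (it is constant per sample).
    """
    sub_x = _feature_slice(tbl, feature_x)
    sub_y = _feature_slice(tbl, feature_y)
    keep = ["sample_id", "patient_id", *group_cols, "value"]
    wide = sub_x[keep].merge(
        sub_y[["sample_id", "value"]], on="sample_id", suffixes=("_x", "_y")
    )
    if wide.empty:
        raise ValidationError(
            f"no samples carry both {feature_x!r} and {feature_y!r}"
        )
    return wide


@dataclass(frozen=True)
class CompositeScoreMatrix:
    """Groups x features matrix of selected-quadrant percentages.

    Each cell is the percent of the group's samples falling in ``quadrant``
    of the (column feature, anchor) scatter, the anchor on the y-axis.
    ``highlight`` is the percent threshold used to mark cells on the heatmap.
    """

    anchor: str
    quadrant: str
    highlight: float
    matrix: pd.DataFrame  # index: group labels, columns: features

    def to_csv(self, path=None):
        return self.matrix.to_csv(path)

    def to_json(self, path=None) -> str:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "type": "CompositeScoreMatrix",
            "anchor": self.anchor,
            "quadrant": self.quadrant,
            "highlight": self.highlight,
            "groups": [str(g) for g in self.matrix.index],
            "features": list(self.matrix.columns),
            "cells": self.matrix.to_numpy().tolist(),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def composite_scores(
    tbl: pd.DataFrame,
    anchor: str,
    columns: Sequence[str],
    thresholds: ThresholdSet,
    group_cols: Sequence[str],
    quadrant: str = "Q2",
    highlight: float = 20.0,
) -> CompositeScoreMatrix:
    """Percent of samples in ``quadrant`` for the anchor against many features.

    One matrix row per group, one column per feature/pathway; cell (g, f) is
    the percent of g's samples with ``classify_quadrant(value_f, value_anchor)``
    equal to ``quadrant`` (anchor on the y-axis). Typically used with Q2
    (high/high) to rank indications for a dual-target therapeutic.
    """
    if quadrant not in QUADRANTS:
        raise ValidationError(f"unknown quadrant {quadrant!r}")
    if anchor in columns:
        raise ValidationError("anchor must not be listed among columns")
    thr_a = thresholds[anchor]
    cols: dict[str, pd.Series] = {}
    for f in columns:
        thr_f = thresholds[f]
        wide = pair_features(tbl, f, anchor, group_cols)
        quad = _classify_quadrants(
            wide["value_x"].to_numpy(), wide["value_y"].to_numpy(), thr_f, thr_a
        )
        wide = wide.assign(hit=(quad == quadrant))
        pct = wide.groupby(list(group_cols), sort=True, observed=True)["hit"].mean() * 100.0
        cols[f] = pct
    matrix = pd.DataFrame(cols)
    if len(group_cols) > 1:
        matrix.index = ["_".join(map(str, ix)) for ix in matrix.index]
    matrix.index.name = "_".join(group_cols)
    return CompositeScoreMatrix(
        anchor=anchor, quadrant=quadrant, highlight=float(highlight), matrix=matrix
    )


# ---------------------------------------------------------------------------
# group comparisons


@dataclass(frozen=True)
class GroupComparison:
    """Two-level (or k-level) comparison of one feature per group.

    ``table``: one row per group with, per split level L, ``n_<L>`` and
    ``pct_above_<L>`` (percent of that level's samples strictly above the
    global threshold), plus ``fold_change`` (linear scale; only for exactly
    two levels), ``kw_stat`` and ``kw_pvalue`` (tie-corrected Kruskal-Wallis,
    chi-square approximation, raw p-value).
    """

    feature: str
    split_col: str
    reference_level: str
    levels: tuple[str, ...]
    threshold: float
    group_cols: tuple[str, ...]
    table: pd.DataFrame

    def to_csv(self, path=None):
        return self.table.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "type": "GroupComparison",
            "feature": self.feature,
            "split_col": self.split_col,
            "reference_level": self.reference_level,
            "levels": list(self.levels),
            "threshold": self.threshold,
            "group_cols": list(self.group_cols),
            "rows": json.loads(self.table.to_json(orient="records")),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def group_compare(
    tbl: pd.DataFrame,
    feature: str,
    split_col: str,
    reference_level: str,
    thresholds: ThresholdSet,
    group_cols: Sequence[str] = (),
) -> GroupComparison:
    """Compare split levels (e.g. database1 vs database2) within each group.

    Fold change is ``2 ** (median(level) - median(reference))`` — inputs are
    log2-scale, the FC is linear-scale — and is reported only when the split
    has exactly two levels. The Kruskal-Wallis test runs on the raw values
    across all levels. Groups where a level is empty are skipped with a
    warning.
    """
    sub = _feature_slice(tbl, feature)
    if split_col not in sub.columns:
        raise ValidationError(f"split column {split_col!r} not in table")
    levels = sorted(map(str, sub[split_col].dropna().unique()))
    if str(reference_level) not in levels:
        raise ValidationError(
            f"reference level {reference_level!r} not among {levels}"
        )
    # reference first, for stable column order
    levels = [str(reference_level)] + [l for l in levels if l != str(reference_level)]
    thr = thresholds[feature]

    if group_cols:
        grouped = sub.groupby(list(group_cols), sort=True, observed=True)
    else:
        grouped = [((), sub)]

    rows = []
    for key, g in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        by_level = {
            l: g.loc[g[split_col].astype(str) == l, "value"].to_numpy(dtype=float)
            for l in levels
        }
        if any(v.size == 0 for v in by_level.values()):
            warnings.warn(
                f"group {key}: empty split level, comparison skipped", stacklevel=2
            )
            continue
        row = dict(zip(group_cols, key))
        for l in levels:
            v = by_level[l]
            row[f"n_{l}"] = int(v.size)
            row[f"pct_above_{l}"] = 100.0 * float((v > thr).sum()) / v.size
        if len(levels) == 2:
            other = levels[1]
            row["fold_change"] = float(
                2.0 ** (np.median(by_level[other]) - np.median(by_level[levels[0]]))
            )
        else:
            row["fold_change"] = float("nan")
        if all(np.ptp(v) == 0 for v in by_level.values()) and len(
            {v[0] for v in by_level.values()}
        ) == 1:
            # identical constant groups: KW is 0 by definition, scipy raises
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.kruskal(*by_level.values())
        row["kw_stat"] = float(stat)
        row["kw_pvalue"] = float(p)
        rows.append(row)
    table = pd.DataFrame(rows)
    return GroupComparison(
        feature=feature,
        split_col=split_col,
        reference_level=str(reference_level),
        levels=tuple(levels),
        threshold=thr,
        group_cols=tuple(group_cols),
        table=table,
    )


def paired_pre_post(
    tbl: pd.DataFrame,
    feature: str,
    time_col: str,
    thresholds: ThresholdSet,
    group_cols: Sequence[str] = (),
    pre_label: str = "pre",
    post_label: str = "post",
    strict: bool = True,
) -> tuple[GroupComparison, pd.DataFrame]:
    """Pre/post-treatment comparison with an explicit patient pairing map.

    Statistics are those of :func:`group_compare` with the time column as the
    split and "pre" as the reference; the Kruskal-Wallis test is kept even
    for paired data (the pairing is used only to draw connector lines on the
    figure). Additionally returns the pairing map — one row per patient with
    ``patient_id``, ``pre_sample``, ``post_sample`` and the group columns.

    Every in-scope patient must have exactly one pre and one post sample;
    violations raise (strict, default) listing the offending patients, or
    drop those patients with a warning (``strict=False``).
    """
    sub = _feature_slice(tbl, feature)
    if time_col not in sub.columns:
        raise ValidationError(f"time column {time_col!r} not in table")
    labels = set(map(str, sub[time_col].dropna().unique()))
    if not {pre_label, post_label} <= labels:
        raise ValidationError(
            f"time column must contain {pre_label!r} and {post_label!r}; found {sorted(labels)}"
        )

    counts = (
        sub.assign(_t=sub[time_col].astype(str))
        .pivot_table(index="patient_id", columns="_t", values="sample_id", aggfunc="count")
        .reindex(columns=[pre_label, post_label], fill_value=0)
        .fillna(0)
    )
    bad = counts.index[(counts[pre_label] != 1) | (counts[post_label] != 1)].tolist()
    if bad:
        if strict:
            raise ValidationError(
                f"unpaired patient(s) for {feature!r}: {sorted(map(str, bad))[:20]}"
            )
        warnings.warn(f"dropping {len(bad)} unpaired patient(s)", stacklevel=2)
        sub = sub[~sub["patient_id"].isin(bad)]

    comparison = group_compare(
        sub,
        feature,
        split_col=time_col,
        reference_level=pre_label,
        thresholds=thresholds,
        group_cols=group_cols,
    )
    pre = sub[sub[time_col].astype(str) == pre_label]
    post = sub[sub[time_col].astype(str) == post_label]
    pairing = pre[["patient_id", "sample_id", *group_cols]].merge(
        post[["patient_id", "sample_id"]], on="patient_id", suffixes=("", "_post")
    )
    pairing = pairing.rename(
        columns={"sample_id": "pre_sample", "sample_id_post": "post_sample"}
    )[["patient_id", "pre_sample", "post_sample", *group_cols]]
    return comparison, pairing


# ---------------------------------------------------------------------------
# quartile bins and clustering


def bin_percent(p: float) -> str:
    """Quartile bin of a percentage: Q1 [0,25), Q2 [25,50), Q3 [50,75), Q4 [75,100]."""
    if not (0.0 <= p <= 100.0):
        raise ValidationError(f"percentage {p} outside [0, 100]")
    if p < 25.0:
        return "Q1"
    if p < 50.0:
        return "Q2"
    if p < 75.0:
        return "Q3"
    return "Q4"


@dataclass(frozen=True)
class ClusterOrder:
    """Deterministic leaf order of a hierarchical clustering.

    ``labels``: row labels in dendrogram leaf order; ``linkage``: the scipy
    linkage matrix; ``distance`` / ``method`` record the metric and linkage
    used, for provenance.
    """

    labels: tuple[str, ...]
    linkage: np.ndarray = field(repr=False)
    distance: str = "euclidean"
    method: str = "complete"


def cluster_order(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    method: str = "complete",
) -> ClusterOrder:
    """Hierarchically cluster matrix rows; return labels in leaf order.

    Euclidean distance with complete linkage by default. Rows with identical
    values merge at distance zero and are therefore adjacent in the order.
    Missing cells are an error: impute or filter first.
    """
    if matrix.shape[0] < 2:
        raise ValidationError("need at least 2 rows to cluster")
    if matrix.isna().any().any():
        raise ValidationError("matrix contains missing cells")
    # condense first: a small square symmetric matrix would otherwise be
    # misread as a pre-computed distance matrix
    condensed = spd.pdist(matrix.to_numpy(dtype=float), metric=distance)
    Z = sch.linkage(condensed, method=method)
    order = sch.leaves_list(Z)
    return ClusterOrder(
        labels=tuple(str(matrix.index[i]) for i in order),
        linkage=Z,
        distance=distance,
        method=method,
    )
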