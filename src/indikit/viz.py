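"""Annotated figure family.

Figures are built in two phases. Each ``plot_*`` function calls the stats
module, assembles a :class:`FigureSpec` — the group ordering, axis labels,
threshold lines and, crucially, every annotation string that will be printed
on the figure — and only then renders it with matplotlib. Every annotation
string is the formatted value of a field in the attached stats result;
nothing is recomputed at render time. Tests therefore target the
``FigureSpec`` payload, not pixels.

Number formatting is centralized here: percentages to 0 decimals on box and
scatter plots ("42%"), 1 decimal in heatmap cells; p-values switch to
scientific notation below 0.001; undefined correlations (n < 3) render as
"r=NA". Threshold lines are drawn dotted in orange, jitter uses a fixed
per-figure seed, and SVG output carries no timestamp, so re-rendering the
same spec is byte-identical.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import stats as _st
from .errors import ValidationError
from .stats import CompositeScoreMatrix, QuadrantResult, ThresholdSet

THRESHOLD_LINE_STYLE = {"color": "darkorange", "linestyle": ":", "linewidth": 1.5}

#: Centralized number formats (see module docstring).
FORMATS = {
    "pct_box": "{:.0f}%",
    "pct_heatmap": "{:.1f}",
    "fc": "FC={:.2f}",
    "corr": "r={:.2f}",
    "n": "n={:d}",
}


def fmt_pct0(p: float) -> str:
    return FORMATS["pct_box"].format(p)


def fmt_pct1(p: float) -> str:
    return FORMATS["pct_heatmap"].format(p)


def fmt_fc(fc: float) -> str:
    return FORMATS["fc"].format(fc)


def fmt_corr(r: float) -> str:
    if r is None or (isinstance(r, float) and math.isnan(r)):
        return "r=NA"
    return FORMATS["corr"].format(r)


def fmt_pval(p: float, label: str = "Pval") -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return f"{label}=NA"
    if p < 0.001:
        return f"{label}={p:.1e}"
    return f"{label}={p:.3f}"


@dataclass
class FigureSpec:
    """Everything a figure will print, before any drawing happens.

    ``annotations`` maps group label -> {slot name -> formatted string};
    ``groups`` fixes the display order (always a permutation of the groups in
    the attached stats object); ``highlight`` flags groups meeting the
    highlight rule; ``stats`` holds the stats result object(s) the
    annotations were formatted from; ``data`` carries the raw plotting
    payload (value arrays, matrices, pairings).
    """

    kind: str
    title: str
    xlabel: str
    ylabel: str
    groups: tuple[str, ...]
    annotations: dict[str, dict[str, str]]
    threshold_lines: dict[str, float] = field(default_factory=dict)
    highlight: dict[str, bool] = field(default_factory=dict)
    stats: Any = None
    data: dict[str, Any] = field(default_factory=dict, repr=False)
    style: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        doc = {
            "kind": self.kind,
            "title": self.title,
            "xlabel": self.xlabel,
            "ylabel": self.ylabel,
            "groups": list(self.groups),
            "annotations": self.annotations,
            "threshold_lines": self.threshold_lines,
            "highlight": self.highlight,
            "style": self.style,
        }
        if self.stats is not None and hasattr(self.stats, "to_json"):
            doc["stats"] = json.loads(self.stats.to_json())
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _group_key(row_or_values, group_cols) -> str:
    if isinstance(row_or_values, tuple):
        return "_".join(str(v) for v in row_or_values)
    if group_cols is None:
        return str(row_or_values)
    return "_".join(str(row_or_values[c]) for c in group_cols)


def _grouped_values(tbl: pd.DataFrame, feature: str, group_cols: Sequence[str]):
    sub = tbl[tbl["feature"] == feature]
    out: dict[str, np.ndarray] = {}
    for key, g in sub.groupby(list(group_cols), sort=True, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        out[_group_key(key, group_cols)] = g["value"].to_numpy(dtype=float)
    return out


def _unit(tbl: pd.DataFrame) -> str:
    u = tbl["unit"].dropna().unique()
    return str(u[0]) if len(u) else "expression"


def _check_plot_groups(available, plot_groups):
    if plot_groups is None:
        return list(available)
    missing = [g for g in plot_groups if g not in available]
    if missing:
        raise ValidationError(f"plot_groups not present in data: {missing}")
    return list(plot_groups)


# ---------------------------------------------------------------------------
# box plots


def plot_expression_box(
    tbl: pd.DataFrame,
    feature: str,
    group_cols: Sequence[str],
    thresholds: ThresholdSet,
    plot_groups: Sequence[str] | None = None,
    out: str | None = None,
) -> FigureSpec:
    """Boxplot of one feature per group with threshold and percent labels.

    One box per group with jittered sample dots, a horizontal line at the
    global threshold, the percent of samples strictly above it printed above
    each box and the group size just above the axis. ``plot_groups`` subsets
    the display only — the threshold and percentages come from the full
    table.
    """
    pa = _st.percent_above(tbl, feature, thresholds[feature], group_cols)
    pa = pa.assign(_key=[_group_key(tuple(r[c] for c in group_cols), group_cols)
                         for _, r in pa.iterrows()])
    values = _grouped_values(tbl, feature, group_cols)
    groups = _check_plot_groups(list(pa["_key"]), plot_groups)

    annotations = {}
    for _, row in pa.set_index("_key").loc[groups].reset_index().iterrows():
        annotations[row["_key"]] = {
            "percent": fmt_pct0(row["percent"]),
            "n": FORMATS["n"].format(int(row["n"])),
        }
    spec = FigureSpec(
        kind="box",
        title=feature,
        xlabel="_".join(group_cols),
        ylabel=f"{feature} ({_unit(tbl)})",
        groups=tuple(groups),
        annotations=annotations,
        threshold_lines={"y": thresholds[feature]},
        stats=None,
        data={"values": {g: values[g] for g in groups}, "percent_above": pa},
        style={"threshold_method": thresholds.method},
    )
    if out:
        render(spec, out)
    return spec


def plot_box_pre_post(
    tbl: pd.DataFrame,
    feature: str,
    group_cols: Sequence[str],
    thresholds: ThresholdSet,
    time_col: str = "treatment",
    strict: bool = True,
    out: str | None = None,
) -> FigureSpec:
    """Paired pre/post boxes per group with patient connector lines.

    Fold change and Kruskal-Wallis p-value are printed above each group; one
    connector per (pre, post) sample pair of a patient.
    """
    comparison, pairing = _st.paired_pre_post(
        tbl, feature, time_col=time_col, thresholds=thresholds,
        group_cols=group_cols, strict=strict,
    )
    sub = tbl[tbl["feature"] == feature]
    values = {}
    for key, g in sub.groupby([*group_cols, time_col], sort=True, observed=True):
        values[_group_key(key, None)] = g["value"].to_numpy(dtype=float)

    annotations = {}
    groups = []
    for _, row in comparison.table.iterrows():
        key = _group_key(tuple(row[c] for c in group_cols), group_cols)
        groups.append(key)
        annotations[key] = {
            "fc": fmt_fc(row["fold_change"]),
            "kw": fmt_pval(row["kw_pvalue"], label="KW p"),
        }
    sample_values = dict(zip(sub["sample_id"], sub["value"]))
    spec = FigureSpec(
        kind="box_pre_post",
        title=feature,
        xlabel="_".join(group_cols),
        ylabel=f"{feature} ({_unit(tbl)})",
        groups=tuple(groups),
        annotations=annotations,
        stats=comparison,
        data={
            "values": values,
            "pairing": pairing,
            "sample_values": sample_values,
            "time_col": time_col,
            "group_cols": list(group_cols),
        },
    )
    if out:
        render(spec, out)
    return spec


def plot_expression_box_split(
    tbl: pd.DataFrame,
    feature: str,
    split_col: str,
    group_cols: Sequence[str],
    thresholds: ThresholdSet,
    reference_level: str | None = None,
    out: str | None = None,
) -> FigureSpec:
    """Side-by-side boxes per split level within each group.

    Prints, per group: percent above the global threshold for each level,
    the fold change between the two levels, the Kruskal-Wallis p-value, and
    each level's sample count; plus the global threshold line.
    """
    sub = tbl[tbl["feature"] == feature]
    if reference_level is None:
        reference_level = sorted(map(str, sub[split_col].dropna().unique()))[0]
    comparison = _st.group_compare(
        tbl, feature, split_col=split_col, reference_level=reference_level,
        thresholds=thresholds, group_cols=group_cols,
    )
    values = {}
    for key, g in sub.groupby([*group_cols, split_col], sort=True, observed=True):
        values[_group_key(key, None)] = g["value"].to_numpy(dtype=float)

    annotations = {}
    groups = []
    for _, row in comparison.table.iterrows():
        key = _group_key(tuple(row[c] for c in group_cols), group_cols)
        groups.append(key)
        ann = {
            "fc": fmt_fc(row["fold_change"]),
            "pval": fmt_pval(row["kw_pvalue"], label="Pval"),
        }
        for level in comparison.levels:
            ann[f"percent_{level}"] = fmt_pct0(row[f"pct_above_{level}"])
            ann[f"n_{level}"] = FORMATS["n"].format(int(row[f"n_{level}"]))
        annotations[key] = ann
    spec = FigureSpec(
        kind="box_split",
        title=feature,
        xlabel="_".join(group_cols),
        ylabel=f"{feature} ({_unit(tbl)})",
        groups=tuple(groups),
        annotations=annotations,
        threshold_lines={"y": thresholds[feature]},
        stats=comparison,
        data={
            "values": values,
            "levels": list(comparison.levels),
            "group_cols": list(group_cols),
        },
    )
    if out:
        render(spec, out)
    return spec


# ---------------------------------------------------------------------------
# scatter


def plot_expression_scatter(
    tbl: pd.DataFrame,
    feature_x: str,
    feature_y: str,
    thresholds: ThresholdSet,
    group_cols: Sequence[str],
    plot_groups: Sequence[str] | None = None,
    quadrant: str = "Q2",
    highlight_pct: float = 40.0,
    corr: str = "spearman",
    color_by: str | None = None,
    out: str | None = None,
) -> FigureSpec:
    """Flow-cytometry-style scatter per group with quadrant gates.

    Gridlines at the two global thresholds split each panel into quadrants;
    each panel prints the percent of its samples per quadrant and the
    correlation with its p-value. Panels whose selected-quadrant percent
    exceeds ``highlight_pct`` are flagged (highlighted title). An optional
    third feature colors the dots.
    """
    if quadrant not in _st.QUADRANTS:
        raise ValidationError(f"unknown quadrant {quadrant!r}")
    qr = _st.quadrant_stats(
        tbl, feature_x, feature_y, thresholds, group_cols, corr=corr
    )
    keys = [
        _group_key(tuple(r[c] for c in group_cols), group_cols)
        for _, r in qr.table.iterrows()
    ]
    qtab = qr.table.assign(_key=keys).set_index("_key")
    groups = _check_plot_groups(keys, plot_groups)

    wide = _st.pair_features(tbl, feature_x, feature_y, group_cols)
    wide = wide.assign(
        _key=[_group_key(tuple(r[c] for c in group_cols), group_cols)
              for _, r in wide.iterrows()]
    )
    color_values = None
    if color_by is not None:
        csub = tbl[tbl["feature"] == color_by]
        if csub.empty:
            raise ValidationError(f"unknown feature {color_by!r}")
        cmap = dict(zip(csub["sample_id"], csub["value"]))
        color_values = wide["sample_id"].map(cmap)

    annotations, highlight = {}, {}
    for g in groups:
        row = qtab.loc[g]
        ann = {f"pct_{q}": fmt_pct0(row[f"pct_{q}"]) for q in _st.QUADRANTS}
        ann["corr"] = fmt_corr(row["corr"])
        ann["pval"] = fmt_pval(row["pvalue"], label="P")
        annotations[g] = ann
        highlight[g] = bool(row[f"pct_{quadrant}"] > highlight_pct)
    spec = FigureSpec(
        kind="scatter",
        title=f"{feature_x} vs {feature_y}",
        xlabel=f"{feature_x} ({_unit(tbl)})",
        ylabel=f"{feature_y} ({_unit(tbl)})",
        groups=tuple(groups),
        annotations=annotations,
        threshold_lines={"x": qr.threshold_x, "y": qr.threshold_y},
        highlight=highlight,
        stats=qr,
        data={"pairs": wide, "color_values": color_values, "color_by": color_by},
        style={"quadrant": quadrant, "highlight_pct": highlight_pct},
    )
    if out:
        render(spec, out)
    return spec


# ---------------------------------------------------------------------------
# heatmaps


def heatmap_sample_expression(
    tbl: pd.DataFrame,
    features: Sequence[str] | None = None,
    group_cols: Sequence[str] = ("indication",),
    split_rows: Mapping[str, Sequence[str]] | None = None,
    order: Sequence[str] | None = None,
    out: str | None = None,
) -> FigureSpec:
    """Mean-expression heatmap (features x groups).

    Cell = mean expression of the feature within the group. Rows can be
    split into blocks by gene-set membership; column order comes from
    hierarchical clustering of the groups unless supplied.
    """
    sub = tbl if features is None else tbl[tbl["feature"].isin(features)]
    if sub.empty:
        raise ValidationError("no features selected")
    keys = [
        _group_key(tuple(r[c] for c in group_cols), group_cols)
        for _, r in sub.iterrows()
    ]
    sub = sub.assign(_key=keys)
    matrix = sub.pivot_table(index="feature", columns="_key", values="value", aggfunc="mean")
    if features is not None:
        matrix = matrix.loc[list(features)]
    if matrix.isna().any().any():
        raise ValidationError("some (feature, group) cells have no samples")
    if order is None:
        if matrix.shape[1] >= 2:
            order = list(_st.cluster_order(matrix.T).labels)
        else:
            order = list(matrix.columns)
    matrix = matrix[list(order)]

    row_breaks: list[int] = []
    if split_rows:
        # regroup rows into contiguous blocks by set membership, leftovers last
        blocks = []
        seen: set[str] = set()
        for members in split_rows.values():
            block = [f for f in members if f in matrix.index and f not in seen]
            seen.update(block)
            if block:
                blocks.append(block)
        rest = [f for f in matrix.index if f not in seen]
        if rest:
            blocks.append(rest)
        matrix = matrix.loc[[f for b in blocks for f in b]]
        edge = 0
        for b in blocks[:-1]:
            edge += len(b)
            row_breaks.append(edge)

    annotations = {
        str(g): {str(f): fmt_pct1(matrix.loc[f, g]) for f in matrix.index}
        for g in matrix.columns
    }
    spec = FigureSpec(
        kind="heatmap_expression",
        title="Mean expression",
        xlabel="_".join(group_cols),
        ylabel="feature",
        groups=tuple(str(g) for g in matrix.columns),
        annotations=annotations,
        stats=None,
        data={"matrix": matrix, "split_rows": split_rows, "row_breaks": row_breaks},
    )
    if out:
        render(spec, out)
    return spec


def heatmap_samples_above_median(
    tbl: pd.DataFrame,
    features: Sequence[str],
    group_cols: Sequence[str],
    thresholds: ThresholdSet,
    out: str | None = None,
) -> FigureSpec:
    """Percent-above-threshold heatmap with quartile-distribution bars.

    Cell = percent of the group's samples strictly above the feature's global
    threshold. The bar above each column shows how many of its features fall
    in each percentage quartile bin (Q1 0-25, Q2 25-50, Q3 50-75, Q4 75-100);
    columns are ordered by hierarchical clustering.
    """
    cols = {}
    for f in features:
        pa = _st.percent_above(tbl, f, thresholds[f], group_cols)
        keys = [
            _group_key(tuple(r[c] for c in group_cols), group_cols)
            for _, r in pa.iterrows()
        ]
        cols[f] = pd.Series(pa["percent"].to_numpy(), index=keys)
    matrix = pd.DataFrame(cols).T  # features x groups
    if matrix.isna().any().any():
        raise ValidationError("some (feature, group) cells have no samples")
    if matrix.shape[1] >= 2:
        order = list(_st.cluster_order(matrix.T).labels)
        matrix = matrix[order]

    bins = {}
    for g in matrix.columns:
        counts = {q: 0 for q in _st.QUADRANTS}
        for f in matrix.index:
            counts[_st.bin_percent(matrix.loc[f, g])] += 1
        bins[str(g)] = counts
    annotations = {
        str(g): {str(f): fmt_pct1(matrix.loc[f, g]) for f in matrix.index}
        for g in matrix.columns
    }
    spec = FigureSpec(
        kind="heatmap_percent",
        title=f"% samples above {thresholds.method} threshold",
        xlabel="_".join(group_cols),
        ylabel="feature",
        groups=tuple(str(g) for g in matrix.columns),
        annotations=annotations,
        stats=None,
        data={"matrix": matrix, "bins": bins},
    )
    if out:
        render(spec, out)
    return spec


def heatmap_composite_scores(
    matrix: CompositeScoreMatrix,
    out: str | None = None,
) -> FigureSpec:
    """Composite-score heatmap: groups x features quadrant percentages.

    Cells are annotated with the percentage (1 decimal); cells at or above
    the matrix's highlight threshold are marked.
    """
    m = matrix.matrix
    if m.size == 0:
        raise ValidationError("empty composite score matrix")
    annotations, marks = {}, {}
    for g in m.index:
        annotations[str(g)] = {str(f): fmt_pct1(m.loc[g, f]) for f in m.columns}
        marks[str(g)] = {str(f): bool(m.loc[g, f] >= matrix.highlight) for f in m.columns}
    spec = FigureSpec(
        kind="heatmap_composite",
        title=f"% samples in {matrix.quadrant} vs {matrix.anchor}",
        xlabel="feature",
        ylabel="group",
        groups=tuple(str(g) for g in m.index),
        annotations=annotations,
        stats=matrix,
        data={"matrix": m, "marks": marks},
        style={"highlight": matrix.highlight},
    )
    if out:
        render(spec, out)
    return spec


def plot_perc_pop(
    qr: QuadrantResult,
    quadrant: str = "Q2",
    out: str | None = None,
) -> FigureSpec:
    """One bar per group: the percent of its samples in the selected quadrant."""
    if quadrant not in _st.QUADRANTS:
        raise ValidationError(f"unknown quadrant {quadrant!r}")
    if qr.table.empty:
        raise ValidationError("empty quadrant result")
    keys = [
        _group_key(tuple(r[c] for c in qr.group_cols), qr.group_cols)
        for _, r in qr.table.iterrows()
    ]
    pct = dict(zip(keys, qr.table[f"pct_{quadrant}"]))
    annotations = {g: {"percent": fmt_pct0(p)} for g, p in pct.items()}
    spec = FigureSpec(
        kind="perc_pop",
        title=f"% samples in {quadrant}: {qr.feature_x} vs {qr.feature_y}",
        xlabel="_".join(qr.group_cols),
        ylabel=f"% samples in {quadrant}",
        groups=tuple(keys),
        annotations=annotations,
        stats=qr,
        data={"percent": pct},
        style={"quadrant": quadrant},
    )
    if out:
        render(spec, out)
    return spec


# ---------------------------------------------------------------------------
# rendering


def _jitter_rng(spec: FigureSpec) -> np.random.Generator:
    key = zlib.crc32(f"{spec.kind}|{spec.title}".encode("utf-8"))
    return np.random.default_rng(key)


def render(spec: FigureSpec, out: str) -> str:
    """Render a FigureSpec to PNG/SVG/PDF chosen by the file extension.

    Deterministic: fixed jitter seed per figure, no embedded timestamps in
    vector output.
    """
    with matplotlib.rc_context({"svg.hashsalt": "indikit"}):
        fig = _draw(spec)
        try:
            if str(out).lower().endswith(".svg"):
                fig.savefig(out, metadata={"Date": None})
            else:
                fig.savefig(out)
        finally:
            plt.close(fig)
    return out


def _annotate_top(ax, positions, labels, fontsize=8):
    ymax = ax.get_ylim()[1]
    for x, lines in zip(positions, labels):
        ax.text(x, ymax, "\n".join(lines), ha="center", va="bottom", fontsize=fontsize)


def _draw(spec: FigureSpec):
    kind = spec.kind
    if kind == "box":
        return _draw_box(spec)
    if kind == "box_pre_post":
        return _draw_box_pre_post(spec)
    if kind == "box_split":
        return _draw_box_split(spec)
    if kind == "scatter":
        return _draw_scatter(spec)
    if kind in ("heatmap_expression", "heatmap_percent"):
        return _draw_heatmap(spec)
    if kind == "heatmap_composite":
        return _draw_heatmap_composite(spec)
    if kind == "perc_pop":
        return _draw_perc_pop(spec)
    raise ValidationError(f"unknown figure kind {kind!r}")


def _draw_box(spec: FigureSpec):
    rng = _jitter_rng(spec)
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(spec.groups) + 1.5), 4.5))
    data = [spec.data["values"][g] for g in spec.groups]
    ax.boxplot(data, positions=range(len(spec.groups)), showfliers=False)
    for i, v in enumerate(data):
        ax.plot(i + rng.uniform(-0.15, 0.15, len(v)), v, ".", ms=3, alpha=0.5)
    if "y" in spec.threshold_lines:
        ax.axhline(spec.threshold_lines["y"], **THRESHOLD_LINE_STYLE)
    ax.set_xticks(range(len(spec.groups)), spec.groups, rotation=90)
    ymin = ax.get_ylim()[0]
    for i, g in enumerate(spec.groups):
        ax.text(i, ymin, spec.annotations[g]["n"], ha="center", va="bottom", fontsize=7)
    _annotate_top(ax, range(len(spec.groups)),
                  [[spec.annotations[g]["percent"]] for g in spec.groups])
    ax.set_title(spec.title, pad=28)
    ax.set_ylabel(spec.ylabel)
    fig.tight_layout()
    return fig


def _draw_box_pre_post(spec: FigureSpec):
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(spec.groups) + 1.5), 4.5))
    values = spec.data["values"]
    pairing = spec.data["pairing"]
    sample_values = spec.data["sample_values"]
    group_cols = spec.data["group_cols"]
    positions, labels = [], []
    for i, g in enumerate(spec.groups):
        x_pre, x_post = 2.0 * i, 2.0 * i + 0.7
        pre = values.get(f"{g}_pre", np.array([]))
        post = values.get(f"{g}_post", np.array([]))
        ax.boxplot([pre, post], positions=[x_pre, x_post], widths=0.5, showfliers=False)
        pk = pairing
        if group_cols:
            mask = np.ones(len(pairing), dtype=bool)
            keys = pairing[group_cols].astype(str).agg("_".join, axis=1)
            mask &= (keys == g).to_numpy()
            pk = pairing[mask]
        for _, row in pk.iterrows():
            ax.plot(
                [x_pre, x_post],
                [sample_values[row["pre_sample"]], sample_values[row["post_sample"]]],
                "-", color="grey", lw=0.3, alpha=0.5,
            )
        positions.append((x_pre + x_post) / 2)
        labels.append([spec.annotations[g]["fc"], spec.annotations[g]["kw"]])
    _annotate_top(ax, positions, labels)
    ax.set_xticks(positions, spec.groups, rotation=90)
    ax.set_title(spec.title, pad=34)
    ax.set_ylabel(spec.ylabel)
    fig.tight_layout()
    return fig


def _draw_box_split(spec: FigureSpec):
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(spec.groups) + 1.5), 4.5))
    values = spec.data["values"]
    levels = spec.data["levels"]
    positions, labels = [], []
    for i, g in enumerate(spec.groups):
        xs = [2.0 * i + 0.7 * j for j in range(len(levels))]
        data = [values.get(f"{g}_{lv}", np.array([])) for lv in levels]
        ax.boxplot(data, positions=xs, widths=0.5, showfliers=False)
        ymin = ax.get_ylim()[0]
        for x, lv in zip(xs, levels):
            ax.text(x, ymin, spec.annotations[g][f"n_{lv}"],
                    ha="center", va="bottom", fontsize=7)
        positions.append(float(np.mean(xs)))
        labels.append([
            " ".join(spec.annotations[g][f"percent_{lv}"] for lv in levels),
            spec.annotations[g]["fc"],
            spec.annotations[g]["pval"],
        ])
    if "y" in spec.threshold_lines:
        ax.axhline(spec.threshold_lines["y"], **THRESHOLD_LINE_STYLE)
    _annotate_top(ax, positions, labels)
    ax.set_xticks(positions, spec.groups, rotation=90)
    ax.set_title(spec.title, pad=40)
    ax.set_ylabel(spec.ylabel)
    fig.tight_layout()
    return fig


def _draw_scatter(spec: FigureSpec):
    n = len(spec.groups)
    ncol = min(4, max(1, n))
    nrow = -(-n // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow), squeeze=False)
    pairs = spec.data["pairs"]
    colors = spec.data.get("color_values")
    for k, g in enumerate(spec.groups):
        ax = axes[k // ncol][k % ncol]
        sub = pairs[pairs["_key"] == g]
        if colors is not None:
            c = colors.loc[sub.index]
            sc = ax.scatter(sub["value_x"], sub["value_y"], c=c, s=8, cmap="viridis")
            fig.colorbar(sc, ax=ax, label=spec.data.get("color_by"))
        else:
            ax.scatter(sub["value_x"], sub["value_y"], s=8, alpha=0.6)
        ax.axvline(spec.threshold_lines["x"], **THRESHOLD_LINE_STYLE)
        ax.axhline(spec.threshold_lines["y"], **THRESHOLD_LINE_STYLE)
        ann = spec.annotations[g]
        corners = {"Q1": (0.02, 0.95), "Q2": (0.98, 0.95), "Q3": (0.02, 0.05), "Q4": (0.98, 0.05)}
        for q, (x, y) in corners.items():
            ax.text(x, y, ann[f"pct_{q}"], transform=ax.transAxes, fontsize=7,
                    ha="left" if x < 0.5 else "right",
                    va="top" if y > 0.5 else "bottom")
        ax.set_title(
            f"{g}\n{ann['corr']}, {ann['pval']}", fontsize=8,
            color="darkorange" if spec.highlight.get(g) else "black",
        )
        ax.set_xlabel(spec.xlabel, fontsize=7)
        ax.set_ylabel(spec.ylabel, fontsize=7)
    for k in range(n, nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    return fig


def _draw_heatmap(spec: FigureSpec):
    matrix = spec.data["matrix"]
    with_bars = spec.kind == "heatmap_percent"
    h = 0.3 * matrix.shape[0] + (2.5 if with_bars else 1.5)
    fig = plt.figure(figsize=(0.5 * matrix.shape[1] + 2.5, h))
    if with_bars:
        gs = fig.add_gridspec(2, 1, height_ratios=[1, 4], hspace=0.05)
        ax_bar = fig.add_subplot(gs[0])
        ax = fig.add_subplot(gs[1])
        bins = spec.data["bins"]
        bottoms = np.zeros(matrix.shape[1])
        for q, color in zip(_st.QUADRANTS, ("#dadaeb", "#9e9ac8", "#6a51a3", "#3f007d")):
            heights = [bins[str(g)][q] for g in matrix.columns]
            ax_bar.bar(range(matrix.shape[1]), heights, bottom=bottoms, label=q, color=color)
            bottoms += heights
        ax_bar.set_xlim(-0.5, matrix.shape[1] - 0.5)
        ax_bar.set_xticks([])
        ax_bar.legend(fontsize=6, ncol=4, loc="upper right")
    else:
        ax = fig.add_subplot(111)
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), [str(c) for c in matrix.columns], rotation=90)
    ax.set_yticks(range(matrix.shape[0]), [str(r) for r in matrix.index])
    for i, f in enumerate(matrix.index):
        for j, g in enumerate(matrix.columns):
            ax.text(j, i, spec.annotations[str(g)][str(f)], ha="center", va="center",
                    fontsize=6, color="white")
    for edge in spec.data.get("row_breaks", []):
        ax.axhline(edge - 0.5, color="white", linewidth=2)
    fig.colorbar(im, ax=ax, shrink=0.7)
    ax.set_title(spec.title, fontsize=9)
    if not with_bars:  # gridspec layout is already explicit
        fig.tight_layout()
    return fig


def _draw_heatmap_composite(spec: FigureSpec):
    matrix = spec.data["matrix"]
    marks = spec.data["marks"]
    fig, ax = plt.subplots(
        figsize=(0.7 * matrix.shape[1] + 2.5, 0.35 * matrix.shape[0] + 1.5)
    )
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap="viridis",
                   vmin=0, vmax=100)
    ax.set_xticks(range(matrix.shape[1]), [str(c) for c in matrix.columns], rotation=90)
    ax.set_yticks(range(matrix.shape[0]), [str(r) for r in matrix.index])
    for i, g in enumerate(matrix.index):
        for j, f in enumerate(matrix.columns):
            marked = marks[str(g)][str(f)]
            ax.text(j, i, spec.annotations[str(g)][str(f)], ha="center", va="center",
                    fontsize=7, color="darkorange" if marked else "white",
                    fontweight="bold" if marked else "normal")
    fig.colorbar(im, ax=ax, shrink=0.7, label="% samples")
    ax.set_title(spec.title, fontsize=9)
    fig.tight_layout()
    return fig


def _draw_perc_pop(spec: FigureSpec):
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(spec.groups) + 1.5), 4))
    pct = [spec.data["percent"][g] for g in spec.groups]
    ax.bar(range(len(spec.groups)), pct)
    for i, g in enumerate(spec.groups):
        ax.text(i, pct[i], spec.annotations[g]["percent"], ha="center", va="bottom",
                fontsize=7)
    ax.set_xticks(range(len(spec.groups)), spec.groups, rotation=90)
    ax.set_ylabel(spec.ylabel)
    ax.set_title(spec.title, fontsize=9)
    ax.set_ylim(0, 105)
    fig.tight_layout()
    return fig
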