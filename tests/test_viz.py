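"""Figure tests target the FigureSpec annotation payload, not pixels."""

import json
import re

import numpy as np
import pandas as pd
import pytest

import indikit as ik
from indikit.stats import QUADRANTS
from conftest import long_table


@pytest.fixture(scope="module")
def small_cohort(sim_table):
    keep = sim_table["indication"].isin(["CRC", "STAD", "PDAC", "BLCA"])
    return sim_table[keep].reset_index(drop=True)


@pytest.fixture(scope="module")
def cohort_thresholds(small_cohort):
    return ik.compute_thresholds(small_cohort, method="median")


def parse_pct(s):
    return float(re.fullmatch(r"(-?[\d.]+)%", s).group(1))


class TestBoxSpecs:
    def test_percent_annotation_matches_percent_above(self):
        tbl = long_table(
            {f"s{i}": {"gA": v} for i, v in enumerate([1.0, 2.0, 3.0, 4.0])},
            grp={f"s{i}": "g" for i in range(4)},
        )
        ts = ik.ThresholdSet(method="median", values={"gA": 2.5}, n={"gA": 4})
        spec = ik.plot_expression_box(tbl, "gA", ["grp"], ts)
        assert spec.annotations["g"]["percent"] == "50%"
        assert spec.annotations["g"]["n"] == "n=4"
        assert spec.threshold_lines["y"] == 2.5

    def test_plot_groups_subsets_display_not_threshold(self, small_cohort, cohort_thresholds):
        spec = ik.plot_expression_box(
            small_cohort, "Tumor target", ["indication"], cohort_thresholds,
            plot_groups=["CRC", "STAD"],
        )
        assert spec.groups == ("CRC", "STAD")
        # threshold is the one computed on the complete table
        assert spec.threshold_lines["y"] == cohort_thresholds["Tumor target"]

    def test_unknown_plot_group_rejected(self, small_cohort, cohort_thresholds):
        with pytest.raises(ik.ValidationError, match="NOPE"):
            ik.plot_expression_box(
                small_cohort, "Tumor target", ["indication"], cohort_thresholds,
                plot_groups=["NOPE"],
            )

    def test_annotation_fidelity_round_trip(self, small_cohort, cohort_thresholds):
        spec = ik.plot_expression_box(
            small_cohort, "Tumor target", ["indication"], cohort_thresholds
        )
        pa = spec.data["percent_above"].set_index("_key")
        for g in spec.groups:
            shown = parse_pct(spec.annotations[g]["percent"])
            assert shown == round(pa.loc[g, "percent"])


class TestPrePostSpecs:
    def test_connector_count_is_pairs(self, small_cohort, cohort_thresholds):
        spec = ik.plot_box_pre_post(
            small_cohort, "Tumor target", ["indication"], cohort_thresholds
        )
        per_ind = spec.data["pairing"].groupby("indication").size()
        assert (per_ind == 50).all()

    def test_post_equals_pre_prints_fc_one(self):
        samples, treat, patient = {}, {}, {}
        for i in range(5):
            for t in ("pre", "post"):
                sid = f"p{i}-{t}"
                samples[sid] = {"gA": float(i)}
                treat[sid] = t
                patient[sid] = f"p{i}"
        tbl = long_table(
            samples, patient_id=patient, treatment=treat,
            grp={s: "g" for s in samples},
        )
        ts = ik.compute_thresholds(tbl, method="median")
        spec = ik.plot_box_pre_post(tbl, "gA", ["grp"], ts)
        assert spec.annotations["g"]["fc"] == "FC=1.00"

    def test_strict_mode_propagates_pairing_error(self, small_cohort, cohort_thresholds):
        broken = small_cohort[small_cohort["sample_id"] != "PT-CRC-0001-PRE"]
        with pytest.raises(ik.ValidationError, match="PT-CRC-0001"):
            ik.plot_box_pre_post(
                broken, "Tumor target", ["indication"], cohort_thresholds
            )

    def test_annotations_match_attached_stats(self, small_cohort, cohort_thresholds):
        spec = ik.plot_box_pre_post(
            small_cohort, "Tumor target", ["indication"], cohort_thresholds
        )
        for _, row in spec.stats.table.iterrows():
            ann = spec.annotations[row["indication"]]
            assert ann["fc"] == f"FC={row['fold_change']:.2f}"


class TestSplitSpecs:
    def test_split_annotations_mirror_group_compare(self, small_cohort, cohort_thresholds):
        spec = ik.plot_expression_box_split(
            small_cohort, "Tumor target", "database", ["indication"],
            cohort_thresholds,
        )
        gc = spec.stats
        for _, row in gc.table.iterrows():
            ann = spec.annotations[row["indication"]]
            assert ann["fc"] == f"FC={row['fold_change']:.2f}"
            for level in gc.levels:
                assert parse_pct(ann[f"percent_{level}"]) == round(
                    row[f"pct_above_{level}"]
                )
                assert ann[f"n_{level}"] == f"n={int(row[f'n_{level}'])}"


class TestScatterSpecs:
    def test_symmetric_four_points_annotate_25(self):
        samples = {
            "a": {"gA": 0.0, "gB": 0.0}, "b": {"gA": 0.0, "gB": 1.0},
            "c": {"gA": 1.0, "gB": 0.0}, "d": {"gA": 1.0, "gB": 1.0},
        }
        tbl = long_table(samples, grp={s: "g" for s in samples})
        ts = ik.ThresholdSet(
            method="median", values={"gA": 0.5, "gB": 0.5}, n={"gA": 4, "gB": 4}
        )
        spec = ik.plot_expression_scatter(tbl, "gA", "gB", ts, ["grp"])
        for q in QUADRANTS:
            assert spec.annotations["g"][f"pct_{q}"] == "25%"

    def test_identity_features_print_rho_one(self):
        samples = {f"s{i}": {"gA": float(i), "gB": float(i)} for i in range(12)}
        tbl = long_table(samples, grp={s: "g" for s in samples})
        ts = ik.compute_thresholds(tbl, method="median")
        spec = ik.plot_expression_scatter(tbl, "gA", "gB", ts, ["grp"])
        assert spec.annotations["g"]["corr"] == "r=1.00"

    def test_undefined_correlation_renders_na(self):
        samples = {"a": {"gA": 0.0, "gB": 1.0}, "b": {"gA": 1.0, "gB": 0.0}}
        tbl = long_table(samples, grp={s: "g" for s in samples})
        ts = ik.ThresholdSet(
            method="median", values={"gA": 0.5, "gB": 0.5}, n={"gA": 2, "gB": 2}
        )
        spec = ik.plot_expression_scatter(tbl, "gA", "gB", ts, ["grp"])
        assert spec.annotations["g"]["corr"] == "r=NA"

    def test_highlight_is_strictly_over_threshold(self, small_cohort, cohort_thresholds):
        spec = ik.plot_expression_scatter(
            small_cohort, "Tumor target", "Immune target", cohort_thresholds,
            ["indication", "treatment"], highlight_pct=40.0,
        )
        qtab = spec.stats.table
        for _, row in qtab.iterrows():
            key = f"{row['indication']}_{row['treatment']}"
            assert spec.highlight[key] == (row["pct_Q2"] > 40.0)


class TestHeatmapSpecs:
    def test_constant_feature_gives_constant_row(self):
        samples = {f"s{i}": {"gA": 1.5, "gB": float(i)} for i in range(6)}
        tbl = long_table(
            samples, grp={f"s{i}": ("x" if i < 3 else "y") for i in range(6)}
        )
        spec = ik.heatmap_sample_expression(tbl, ["gA", "gB"], ["grp"])
        row = spec.data["matrix"].loc["gA"]
        assert (row == 1.5).all()

    def test_column_order_comes_from_cluster_order(self, small_cohort):
        spec = ik.heatmap_sample_expression(
            small_cohort, ["Tumor target", "Immune target"], ["indication"]
        )
        matrix = small_cohort.pivot_table(
            index="feature", columns="indication", values="value", aggfunc="mean"
        ).loc[["Tumor target", "Immune target"]]
        expected = ik.cluster_order(matrix.T).labels
        assert spec.groups == expected

    def test_split_rows_groups_features_into_contiguous_blocks(self, small_cohort):
        sets = {"SetA": ["TCA_g01", "TCA_g02"], "SetB": ["NKS_g01"]}
        feats = ["NKS_g01", "Tumor target", "TCA_g01", "TCA_g02"]
        spec = ik.heatmap_sample_expression(
            small_cohort, feats, ["indication"], split_rows=sets
        )
        rows = list(spec.data["matrix"].index)
        assert rows == ["TCA_g01", "TCA_g02", "NKS_g01", "Tumor target"]
        assert spec.data["row_breaks"] == [2, 3]

    def test_all_below_threshold_means_all_mass_in_bin_q1(self):
        samples = {f"s{i}": {"gA": 0.0, "gB": 0.0} for i in range(4)}
        tbl = long_table(
            samples, grp={f"s{i}": ("x" if i < 2 else "y") for i in range(4)}
        )
        ts = ik.ThresholdSet(
            method="median", values={"gA": 1.0, "gB": 1.0}, n={"gA": 4, "gB": 4}
        )
        spec = ik.heatmap_samples_above_median(tbl, ["gA", "gB"], ["grp"], ts)
        assert (spec.data["matrix"].to_numpy() == 0).all()
        for g, bins in spec.data["bins"].items():
            assert bins == {"Q1": 2, "Q2": 0, "Q3": 0, "Q4": 0}

    def test_bin_histogram_conserves_feature_count(self, small_cohort, cohort_thresholds):
        feats = ["Tumor target", "Immune target", "TCA_g01", "NKS_g01"]
        spec = ik.heatmap_samples_above_median(
            small_cohort, feats, ["indication"], cohort_thresholds
        )
        for bins in spec.data["bins"].values():
            assert sum(bins.values()) == len(feats)

    def test_heatmap_cells_round_trip_to_percent_above(self, small_cohort, cohort_thresholds):
        feats = ["Tumor target", "Immune target"]
        spec = ik.heatmap_samples_above_median(
            small_cohort, feats, ["indication"], cohort_thresholds
        )
        for f in feats:
            pa = ik.percent_above(
                small_cohort, f, cohort_thresholds[f], ["indication"]
            ).set_index("indication")
            for g in spec.groups:
                assert float(spec.annotations[g][f]) == pytest.approx(
                    pa.loc[g, "percent"], abs=0.05
                )


class TestCompositeHeatmap:
    def _matrix(self, cells, highlight=20.0):
        m = pd.DataFrame(cells, index=["g1", "g2"], columns=["f1", "f2"])
        return ik.CompositeScoreMatrix(
            anchor="anchor", quadrant="Q2", highlight=highlight, matrix=m
        )

    def test_marking_threshold(self):
        csm = self._matrix([[21.0, 19.0], [20.0, 0.0]])
        spec = ik.heatmap_composite_scores(csm)
        assert spec.data["marks"]["g1"]["f1"] is True
        assert spec.data["marks"]["g1"]["f2"] is False
        assert spec.data["marks"]["g2"]["f1"] is True  # at threshold counts

    def test_all_zero_matrix_has_no_marks(self):
        spec = ik.heatmap_composite_scores(self._matrix([[0.0, 0.0], [0.0, 0.0]]))
        assert not any(v for row in spec.data["marks"].values() for v in row.values())

    def test_cell_annotations_one_decimal(self):
        spec = ik.heatmap_composite_scores(self._matrix([[12.34, 0.0], [50.0, 99.96]]))
        assert spec.annotations["g1"]["f1"] == "12.3"
        assert spec.annotations["g2"]["f2"] == "100.0"


class TestPercPop:
    def test_values_equal_quadrant_percentages(self, small_cohort, cohort_thresholds):
        qr = ik.quadrant_stats(
            small_cohort, "Tumor target", "Immune target", cohort_thresholds,
            ["indication"],
        )
        spec = ik.plot_perc_pop(qr, quadrant="Q2")
        for _, row in qr.table.iterrows():
            assert spec.data["percent"][row["indication"]] == row["pct_Q2"]
            assert parse_pct(spec.annotations[row["indication"]]["percent"]) == round(
                row["pct_Q2"]
            )

    def test_empty_selection_rejected(self):
        qr = ik.QuadrantResult(
            feature_x="a", feature_y="b", threshold_x=0, threshold_y=0,
            corr_method="spearman", group_cols=("grp",), table=pd.DataFrame(),
        )
        with pytest.raises(ik.ValidationError):
            ik.plot_perc_pop(qr)

    def test_ordering_stable_under_rebuild(self, small_cohort, cohort_thresholds):
        qr = ik.quadrant_stats(
            small_cohort, "Tumor target", "Immune target", cohort_thresholds,
            ["indication"],
        )
        assert ik.plot_perc_pop(qr).groups == ik.plot_perc_pop(qr).groups


class TestRendering:
    def test_formats_render_by_extension(self, tmp_path, small_cohort, cohort_thresholds):
        spec = ik.plot_expression_box(
            small_cohort, "Tumor target", ["indication"], cohort_thresholds
        )
        for ext in ("png", "svg", "pdf"):
            out = tmp_path / f"fig.{ext}"
            ik.render(spec, str(out))
            assert out.stat().st_size > 0

    def test_revendering_svg_is_byte_identical(self, tmp_path, small_cohort, cohort_thresholds):
        spec = ik.plot_expression_box(
            small_cohort, "Tumor target", ["indication"], cohort_thresholds
        )
        a, b = tmp_path / "a.svg", tmp_path / "b.svg"
        ik.render(spec, str(a))
        ik.render(spec, str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_spec_serializes_to_json(self, small_cohort, cohort_thresholds):
        spec = ik.plot_expression_scatter(
            small_cohort, "Tumor target", "Immune target", cohort_thresholds,
            ["indication"],
        )
        doc = json.loads(spec.to_json())
        assert doc["kind"] == "scatter"
        assert set(doc["groups"]) == set(spec.groups)
        assert doc["annotations"] == spec.annotations
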