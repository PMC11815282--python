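import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps

from indikit import (
    ValidationError,
    classify_quadrant,
    composite_scores,
    compute_thresholds,
    quadrant_stats,
)
from indikit.stats import QUADRANTS, ThresholdSet, _corr_with_pvalue
from conftest import long_table, random_table


def brute_force_quadrants(points, thr_x, thr_y):
    """Independent per-point oracle: literal transcription of the gating rule."""
    counts = {"Q1": 0, "Q2": 0, "Q3": 0, "Q4": 0}
    for x, y in points:
        if x > thr_x and y > thr_y:
            counts["Q2"] += 1
        elif x <= thr_x and y > thr_y:
            counts["Q1"] += 1
        elif x <= thr_x and y <= thr_y:
            counts["Q3"] += 1
        else:
            counts["Q4"] += 1
    return counts


class TestClassifyQuadrant:
    def test_high_high_is_q2(self):
        assert classify_quadrant(1.0, 1.0, 0.0, 0.0) == "Q2"

    @pytest.mark.parametrize(
        "x,y,expected",
        [(0.0, 0.0, "Q3"),     # both on boundary -> low side
         (1.0, 0.0, "Q4"),     # y on boundary -> low side
         (0.0, 1.0, "Q1"),
         (-1.0, -1.0, "Q3")],
    )
    def test_boundaries_fall_low(self, x, y, expected):
        assert classify_quadrant(x, y, 0.0, 0.0) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            classify_quadrant(float("nan"), 0.0, 0.0, 0.0)

    def test_partitions_the_plane(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            x, y = rng.normal(size=2)
            q = classify_quadrant(x, y, 0.3, -0.2)
            assert q in QUADRANTS


def _thr(tx, ty):
    return ThresholdSet(method="median", values={"gA": tx, "gB": ty}, n={"gA": 0, "gB": 0})


class TestQuadrantStats:
    def test_identical_features_land_in_q2_or_q3(self):
        samples = {f"s{i}": {"gA": float(i), "gB": float(i)} for i in range(8)}
        tbl = long_table(samples, grp={f"s{i}": "g" for i in range(8)})
        ts = compute_thresholds(tbl, method="median")
        qr = quadrant_stats(tbl, "gA", "gB", ts, ["grp"])
        row = qr.table.iloc[0]
        assert row["pct_Q2"] + row["pct_Q3"] == 100.0
        assert row["pct_Q1"] == row["pct_Q4"] == 0.0
        assert row["corr"] == pytest.approx(1.0)

    def test_symmetric_four_points(self):
        samples = {
            "a": {"gA": 0.0, "gB": 0.0},
            "b": {"gA": 0.0, "gB": 1.0},
            "c": {"gA": 1.0, "gB": 0.0},
            "d": {"gA": 1.0, "gB": 1.0},
        }
        tbl = long_table(samples, grp={s: "g" for s in samples})
        qr = quadrant_stats(tbl, "gA", "gB", _thr(0.5, 0.5), ["grp"])
        row = qr.table.iloc[0]
        for q in QUADRANTS:
            assert row[f"pct_{q}"] == 25.0

    def test_seven_points_match_brute_force(self):
        pts = [(-1.2, 0.4), (0.3, 0.3), (0.3, -0.1), (2.0, 2.0),
               (0.0, 0.0), (-0.5, -0.5), (1.0, -1.0)]
        samples = {f"s{i}": {"gA": x, "gB": y} for i, (x, y) in enumerate(pts)}
        tbl = long_table(samples, grp={f"s{i}": "g" for i in range(7)})
        qr = quadrant_stats(tbl, "gA", "gB", _thr(0.0, 0.0), ["grp"])
        expected = brute_force_quadrants(pts, 0.0, 0.0)
        row = qr.table.iloc[0]
        for q in QUADRANTS:
            assert row[f"n_{q}"] == expected[q]

    def test_small_group_reports_counts_but_nan_corr(self):
        samples = {"a": {"gA": 0.0, "gB": 1.0}, "b": {"gA": 1.0, "gB": 0.0}}
        tbl = long_table(samples, grp={s: "g" for s in samples})
        qr = quadrant_stats(tbl, "gA", "gB", _thr(0.5, 0.5), ["grp"])
        row = qr.table.iloc[0]
        assert row["n"] == 2
        assert math.isnan(row["corr"]) and math.isnan(row["pvalue"])

    def test_counts_and_percentages_consistent_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            tbl = random_table(rng, int(rng.integers(4, 15)))
            ts = compute_thresholds(tbl, method="median")
            qr = quadrant_stats(tbl, "gA", "gB", ts, ["grp"])
            assert (qr.table[[f"n_{q}" for q in QUADRANTS]].sum(axis=1)
                    == qr.table["n"]).all()
            assert np.allclose(
                qr.table[[f"pct_{q}" for q in QUADRANTS]].sum(axis=1), 100.0
            )


class TestCorrelation:
    def test_matches_scipy_at_large_n(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.normal(size=(2, 25))
            r, p = _corr_with_pvalue(x, y, "spearman")
            ref = sps.spearmanr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)
            r2, p2 = _corr_with_pvalue(x, y, "pearson")
            ref2 = sps.pearsonr(x, y)
            assert r2 == pytest.approx(ref2.statistic, abs=1e-12)
            assert p2 == pytest.approx(ref2.pvalue, rel=1e-9)

    def test_exact_permutation_p_for_perfect_monotone_small_n(self):
        # only the identity and the reversal of 5 distinct values reach |rho|=1
        x = np.arange(5.0)
        r, p = _corr_with_pvalue(x, x.copy(), "spearman")
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(5))

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 30))
        r1, _ = _corr_with_pvalue(x, y, "spearman")
        r2, _ = _corr_with_pvalue(np.exp(x), y, "spearman")
        assert abs(r1 - r2) < 1e-12

    def test_constant_vector_gives_nan(self):
        r, p = _corr_with_pvalue(np.ones(12), np.arange(12.0), "spearman")
        assert math.isnan(r) and math.isnan(p)


class TestCompositeScores:
    def _sim(self, rng, n=30):
        feats = ("anchor", "f1", "f2")
        samples = {}
        groups = {}
        for i in range(n):
            sid = f"s{i}"
            samples[sid] = {f: float(rng.normal()) for f in feats}
            groups[sid] = f"g{i % 2}"
        return long_table(samples, grp=groups)

    def test_cells_match_quadrant_stats(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            tbl = self._sim(rng)
            ts = compute_thresholds(tbl, method="median")
            for quadrant in QUADRANTS:
                csm = composite_scores(
                    tbl, "anchor", ["f1", "f2"], ts, ["grp"], quadrant=quadrant
                )
                for f in ("f1", "f2"):
                    qr = quadrant_stats(tbl, f, "anchor", ts, ["grp"])
                    for _, row in qr.table.iterrows():
                        assert csm.matrix.loc[row["grp"], f] == pytest.approx(
                            row[f"pct_{quadrant}"]
                        )

    def test_identical_column_collapses_to_percent_above(self):
        rng = np.random.default_rng(12)
        tbl = self._sim(rng)
        dup = tbl[tbl.feature == "anchor"].assign(feature="twin")
        tbl = __import__("pandas").concat([tbl, dup], ignore_index=True)
        ts = compute_thresholds(tbl, method="median")
        csm = composite_scores(tbl, "anchor", ["twin"], ts, ["grp"], quadrant="Q2")
        from indikit import percent_above

        pa = percent_above(tbl, "anchor", ts["anchor"], ["grp"])
        for _, row in pa.iterrows():
            assert csm.matrix.loc[row["grp"], "twin"] == pytest.approx(row["percent"])

    def test_anchor_among_columns_rejected(self):
        rng = np.random.default_rng(13)
        tbl = self._sim(rng)
        ts = compute_thresholds(tbl, method="median")
        with pytest.raises(ValidationError, match="anchor"):
            composite_scores(tbl, "anchor", ["anchor", "f1"], ts, ["grp"])

    def test_cells_bounded(self):
        rng = np.random.default_rng(14)
        tbl = self._sim(rng)
        ts = compute_thresholds(tbl, method="median")
        csm = composite_scores(tbl, "anchor", ["f1", "f2"], ts, ["grp"])
        assert ((csm.matrix >= 0) & (csm.matrix <= 100)).all().all()
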