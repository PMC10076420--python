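"""Neighbourhood features: kNN exactness, diversity formulas, NNI, table schema."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from laminar.neighborhood import (
    SpatialIndex,
    build_feature_table,
    distance_stats,
    hull_features,
    neighbor_aggregate,
    nni,
    shannon,
    simpson,
    slice_proportions,
)


def brute_force_knn(points, i, k):
    d = np.hypot(*(points - points[i]).T)
    j = np.arange(len(points))
    keep = j != i
    order = np.lexsort((j[keep], d[keep]))[:k]
    return j[keep][order], d[keep][order]


class TestKnn:
    def test_collinear_points(self):
        idx = SpatialIndex(np.array([[0.0, 0], [1, 0], [3, 0]]))
        j, d = idx.knn(0, 2)
        assert j.tolist() == [1, 2]
        assert d.tolist() == [1.0, 3.0]

    def test_matches_brute_force_on_random_instances(self, uniform_points):
        idx = SpatialIndex(uniform_points)
        rng = np.random.default_rng(0)
        for i in rng.integers(0, len(uniform_points), 20):
            j, d = idx.knn(int(i), 50)
            jb, db = brute_force_knn(uniform_points, int(i), 50)
            assert j.tolist() == jb.tolist()
            np.testing.assert_allclose(d, db)

    def test_duplicate_coordinates_returned_first_by_id(self):
        pts = np.array([[5.0, 5], [5, 5], [5, 5], [20, 5], [9, 5]])
        idx = SpatialIndex(pts)
        j, d = idx.knn(0, 3)
        assert j.tolist() == [1, 2, 4]
        assert d.tolist() == [0.0, 0.0, 4.0]

    def test_k_truncated_when_too_large(self):
        idx = SpatialIndex(np.arange(10, dtype=float).reshape(5, 2))
        j, _ = idx.knn(0, 99)
        assert len(j) == 4

    def test_tie_at_cutoff_broken_by_id(self):
        # two points exactly at distance 1 from the query; k=1 must take lower id
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [5, 5]])
        idx = SpatialIndex(pts)
        j, d = idx.knn(0, 1)
        assert j.tolist() == [1]
        assert d[0] == 1.0


class TestDistanceStats:
    def test_degenerate_all_equal(self):
        s = distance_stats([5.0, 5.0, 5.0, 5.0])
        assert (s["kth"], s["mean"], s["max"], s["min"]) == (5, 5, 5, 5)
        assert s["skew"] == s["kurt"] == s["entropy"] == 0.0
        assert s["degenerate"]

    def test_simple_sample(self):
        s = distance_stats([1.0, 2.0, 3.0, 4.0])
        assert s["mean"] == 2.5
        assert s["max"] == 4 and s["min"] == 1 and s["kth"] == 4

    def test_uniform_sample_entropy_near_log_bins(self):
        rng = np.random.default_rng(1)
        s = distance_stats(rng.uniform(0, 10, 1000))
        assert s["entropy"] == pytest.approx(np.log(10), abs=0.1)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            distance_stats([1.0])


class TestNeighborAggregate:
    def test_constant_field(self, uniform_points):
        idx = SpatialIndex(uniform_points)
        values = np.full(len(uniform_points), 7.5)
        for i in (0, 10, 499):
            assert neighbor_aggregate(idx, values, i, 20, "mean") == pytest.approx(7.5)

    def test_two_band_pattern_recovers_band_mean(self):
        rng = np.random.default_rng(5)
        top = rng.uniform([0, 0], [1000, 500], (800, 2))
        bottom = rng.uniform([0, 500], [1000, 1000], (800, 2))
        pts = np.vstack([top, bottom])
        areas = np.r_[rng.normal(50, 5, 800), rng.normal(200, 20, 800)]
        idx = SpatialIndex(pts)
        interior_top = np.nonzero((top[:, 1] > 100) & (top[:, 1] < 350))[0][:20]
        for i in interior_top:
            got = neighbor_aggregate(idx, areas, int(i), 50, "mean")
            assert got == pytest.approx(50, rel=0.1)

    def test_truncation_when_k_exceeds_n(self):
        idx = SpatialIndex(np.arange(10, dtype=float).reshape(5, 2))
        v = np.arange(5, dtype=float)
        got = neighbor_aggregate(idx, v, 0, 50, "mean")
        assert got == pytest.approx(v[1:].mean())

    def test_absent_values_skipped(self, uniform_points):
        idx = SpatialIndex(uniform_points)
        v = np.full(len(uniform_points), 3.0)
        v[::11] = np.nan
        got = neighbor_aggregate(idx, v, 0, 30, "median")
        assert got == 3.0


class TestHullAndNni:
    def test_unit_square_hull_from_center(self):
        pts = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1], [0.5, 0.5]])
        idx = SpatialIndex(pts)
        hf = hull_features(idx, 4, 4)
        assert hf["hull_area"] == pytest.approx(1.0)
        assert hf["hull_perimeter"] == pytest.approx(4.0)
        assert not hf["degenerate"]

    def test_collinear_neighbourhood_flagged(self):
        pts = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        idx = SpatialIndex(pts)
        hf = hull_features(idx, 0, 4)
        assert hf["degenerate"]
        assert hf["hull_area"] == 0.0

    def test_hull_area_grows_with_k(self, uniform_points):
        idx = SpatialIndex(uniform_points)
        center = int(np.argmin(((uniform_points - 500) ** 2).sum(1)))
        areas = [hull_features(idx, center, k)["hull_area"] for k in (20, 60, 180)]
        assert areas[0] < areas[1] < areas[2]

    def test_nni_scale_invariant(self, uniform_points):
        idx1 = SpatialIndex(uniform_points)
        idx2 = SpatialIndex(uniform_points * 37.5)
        assert nni(idx1, 3, 40) == pytest.approx(nni(idx2, 3, 40), rel=1e-9)
        assert nni(idx1, 3, 40, variant="raw") == pytest.approx(
            nni(idx2, 3, 40, variant="raw"), rel=1e-9
        )

    def test_nni_regimes(self):
        # hexagonal lattice -> dispersed (> 1.5)
        s = 10.0
        rows = []
        for r in range(40):
            for c in range(40):
                rows.append((c * s + (r % 2) * s / 2, r * s * np.sqrt(3) / 2))
        lattice = SpatialIndex(np.array(rows))
        center = int(np.argmin(((lattice.points - lattice.points.mean(0)) ** 2).sum(1)))
        assert nni(lattice, center, 100) > 1.5
        # tight clusters inside a large hull -> clustered (< 0.5)
        rng = np.random.default_rng(0)
        centers = rng.uniform(0, 1000, (150, 2))
        pts = centers[np.repeat(np.arange(150), 10)] + rng.normal(0, 2, (1500, 2))
        clustered = SpatialIndex(pts)
        vals = [nni(clustered, i, 100) for i in range(0, 1500, 50)]
        assert np.mean(vals) < 0.5


class TestSlices:
    def test_eight_even_directions(self):
        angles = np.deg2rad(np.arange(8) * 45.0 + 10)
        pts = np.vstack([[0, 0], np.column_stack([np.cos(angles), np.sin(angles)])])
        idx = SpatialIndex(pts)
        p = slice_proportions(idx, 0, 8, R=8)
        np.testing.assert_allclose(p, 1 / 8)

    def test_all_neighbours_due_east(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        idx = SpatialIndex(pts)
        p = slice_proportions(idx, 0, 3, R=4)
        np.testing.assert_allclose(p, [1, 0, 0, 0])

    def test_isotropic_neighbourhood_near_uniform(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([[0.0, 0.0], rng.normal(0, 100, (800, 2))])
        idx = SpatialIndex(pts)
        p = slice_proportions(idx, 0, 500, R=8)
        assert np.abs(p - 1 / 8).max() < 0.05

    def test_coincident_neighbour_goes_to_sector_zero(self):
        pts = np.array([[0.0, 0], [0, 0], [0, 1]])
        idx = SpatialIndex(pts)
        p = slice_proportions(idx, 0, 2, R=4)
        assert p[0] >= 0.5


class TestDiversityIndices:
    @pytest.mark.parametrize(
        "p, expected_shannon, expected_simpson",
        [
            ([0.25, 0.25, 0.25, 0.25], np.log(4), 0.25),
            ([1.0, 0, 0, 0], 0.0, 1.0),
            ([0.5, 0.5, 0, 0], np.log(2), 0.5),
        ],
    )
    def test_closed_forms(self, p, expected_shannon, expected_simpson):
        assert shannon(p) == pytest.approx(expected_shannon, abs=1e-12)
        assert simpson(p) == pytest.approx(expected_simpson, abs=1e-12)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            shannon([0.5, 0.2])
        with pytest.raises(ValueError):
            simpson([-0.1, 1.1])

    @given(st.lists(st.floats(0.001, 1.0), min_size=2, max_size=12))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_geometric_mean_identity_and_bounds(self, raw):
        """Both closed forms of the Shannon index agree; bounds hold."""
        p = np.array(raw) / np.sum(raw)
        p = p / p.sum()
        h = shannon(p)
        alt = np.log(1.0 / np.prod(p**p))
        assert h == pytest.approx(alt, abs=1e-12)
        R = len(p)
        assert -1e-12 <= h <= np.log(R) + 1e-12
        assert 1 / R - 1e-12 <= simpson(p) <= 1 + 1e-12


class TestFeatureTable:
    def test_schema_and_finiteness(self, small_scene, small_features):
        records, _ = small_scene
        table = small_features
        assert len(table) == len(records)
        for k in (50, 100, 250):
            for stat in ("kth", "mean", "max", "min", "skew", "kurt", "entropy"):
                assert f"{k}_dist_{stat}" in table.columns
            for fam in ("area", "circ", "round", "feret"):
                for stat in ("mean", "median", "sd"):
                    assert f"{k}_{fam}_{stat}" in table.columns
            for c in ("hull_area", "hull_perimeter", "hull_nn_mean", "hull_nn_sd", "nni"):
                assert f"{k}_{c}" in table.columns
            assert f"{k}_shannon_8" in table.columns
            assert f"{k}_simpson_8" in table.columns
        # diversity bounds on real data
        assert table["100_shannon_8"].between(0, np.log(8) + 1e-9).all()
        assert table["100_simpson_8"].between(1 / 8 - 1e-9, 1).all()
        # distance ordering invariant
        assert (table["100_dist_min"] <= table["100_dist_mean"] + 1e-12).all()
        assert (table["100_dist_mean"] <= table["100_dist_max"] + 1e-12).all()
        assert (table["50_dist_kth"] <= table["250_dist_kth"]).all()
        assert np.isfinite(table.to_numpy(float)).all()

    def test_no_gray_columns_by_default(self, small_features):
        assert not [c for c in small_features.columns if c.startswith("gray")]

    def test_deterministic_rebuild(self, small_scene):
        records, _ = small_scene
        t1 = build_feature_table(records.head(400), K=[50], R=8)
        t2 = build_feature_table(records.head(400), K=[50], R=8)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_feature_table(pd.DataFrame(columns=["id", "x_um", "y_um"]))

    def test_k_truncated_for_small_n(self, small_scene):
        records, _ = small_scene
        t = build_feature_table(records.head(40), K=[20, 500], R=8)
        assert "20_dist_mean" in t.columns
        assert "500_dist_mean" not in t.columns

    def test_csv_round_trip_preserves_values(self, small_scene, tmp_path):
        from laminar.neighborhood import load_feature_table, save_feature_table

        records, _ = small_scene
        table = build_feature_table(records.head(200), K=[50], R=8)
        path = tmp_path / "features.csv"
        save_feature_table(table, path)
        assert path.with_suffix(".csv.provenance.json").exists()
        reread = load_feature_table(path)
        pd.testing.assert_frame_equal(table, reread, check_exact=False, rtol=1e-14)

    def test_batch_nni_matches_per_neuron_api(self, small_scene):
        records, _ = small_scene
        sub = records.head(300).reset_index(drop=True)
        table = build_feature_table(sub, K=[50], R=8)
        idx = SpatialIndex(sub[["x_um", "y_um"]].to_numpy())
        for i in (0, 57, 123, 299):
            expected = nni(idx, i, 50)
            got = table["50_nni"].iloc[i]
            assert got == pytest.approx(expected, rel=1e-9)
            hf = hull_features(idx, i, 50)
            assert table["50_hull_area"].iloc[i] == pytest.approx(hf["hull_area"], rel=1e-9)
            assert table["50_hull_nn_mean"].iloc[i] == pytest.approx(hf["hull_nn_mean"], rel=1e-9)
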