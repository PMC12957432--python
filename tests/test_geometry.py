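"""Segmentation, collision-limited expansion, assignment, raster oracle."""

import math

import numpy as np
import pytest
import shapely
from shapely.geometry import Point

from isletquant import (
    AnalysisParams,
    IsletAnnotation,
    SimulationConfig,
    assign_cells,
    expand_islets,
    generate_section,
    raster_oracle,
    segment_islets,
)

ANNULUS_500PI = 500.0 * math.pi  # ring area of a radius-20 circle grown 10 µm


def circle(x, y, r, islet_id=1):
    return IsletAnnotation(islet_id, Point(x, y).buffer(r, quad_segs=64))


class TestSegmentIslets:
    def test_tight_triangle_becomes_one_islet_containing_all_cells(self):
        pts = np.array([[0.0, 0.0], [5.0, 0.0], [2.5, 4.33]])
        params = AnalysisParams(cluster_radius=15.0, cluster_min_cells=3)
        islets = segment_islets(pts, params)
        assert len(islets) == 1
        assert all(islets[0].polygon.covers(Point(*p)) for p in pts)

    def test_no_endocrine_cells_gives_empty_list(self):
        assert segment_islets(np.empty((0, 2)), AnalysisParams()) == []

    def test_area_filter_excludes_below_and_keeps_above_the_floor(self):
        """A single-point cluster closes to a disc of radius r/2, area
        pi*(r/2)^2 — an analytic handle on the area filter."""
        pts = np.array([[100.0, 100.0]])
        disc_area = math.pi * 10.0**2  # r = 20 -> disc radius 10
        below = AnalysisParams(cluster_radius=20.0, cluster_min_cells=1, min_islet_area=disc_area * 1.02)
        above = AnalysisParams(cluster_radius=20.0, cluster_min_cells=1, min_islet_area=disc_area * 0.98)
        assert segment_islets(pts, below) == []
        kept = segment_islets(pts, above)
        assert len(kept) == 1
        assert kept[0].area == pytest.approx(disc_area, rel=0.01)

    def test_ids_are_sequential_in_scanline_order(self):
        rng = np.random.default_rng(0)
        blobs = [rng.normal((x, y), 4.0, size=(20, 2)) for x, y in [(50, 300), (300, 50), (50, 50)]]
        islets = segment_islets(np.vstack(blobs), AnalysisParams())
        assert [i.islet_id for i in islets] == [1, 2, 3]
        miny = [i.polygon.bounds[1] for i in islets]
        assert miny == sorted(miny)

    def test_segmentation_recovers_truth_islets_one_to_one(self):
        """Pooled over 10 seeds, ≥95% of truth islets match exactly one
        segmented polygon with centroid distance under 10 µm."""
        total = matched = 0
        for seed in range(10):
            ds = generate_section(
                SimulationConfig(
                    n_islets=30, section_width=3200.0, section_height=3200.0, seed=seed
                )
            )
            endocrine = ds.cells[ds.cells["true_label"].isin(["beta", "alpha"])]
            segmented = segment_islets(endocrine[["x_um", "y_um"]].to_numpy(), AnalysisParams())
            for truth in ds.islets_truth:
                c = truth.polygon.centroid
                near = [s for s in segmented if s.polygon.centroid.distance(c) < 10.0]
                total += 1
                matched += len(near) == 1
        assert matched / total >= 0.95


class TestExpandIslets:
    def test_single_circle_band_is_the_annulus(self):
        band = expand_islets([circle(0, 0, 20)], AnalysisParams())[0]
        assert band.area == pytest.approx(ANNULUS_500PI, rel=1e-3)

    def test_two_colliding_circles_split_at_the_midline(self):
        # radius 10, boundaries 12 µm apart: bands truncate at the bisector
        islets = [circle(0, 0, 10, 1), circle(32, 0, 10, 2)]
        bands = expand_islets(islets, AnalysisParams())
        full_ring = math.pi * (20.0**2 - 10.0**2)
        assert bands[0].area == pytest.approx(bands[1].area, rel=0.01)  # symmetry
        assert bands[0].area < full_ring
        oracle = raster_oracle(islets, AnalysisParams(raster_resolution=0.25))
        for b in bands:
            assert b.area == pytest.approx(oracle[b.islet_id], rel=0.01)

    def test_distant_islets_keep_their_full_rings(self):
        islets = [circle(0, 0, 15, 1), circle(200, 0, 15, 2)]
        bands = expand_islets(islets, AnalysisParams())
        for isl, band in zip(islets, bands):
            ring = isl.polygon.buffer(10.0, quad_segs=16).difference(isl.polygon)
            assert band.area == pytest.approx(ring.area, rel=1e-9)

    def test_overlapping_input_islets_are_rejected(self):
        islets = [circle(0, 0, 20, 1), circle(10, 0, 20, 2)]
        with pytest.raises(ValueError, match="interior-disjoint"):
            expand_islets(islets, AnalysisParams())

    def test_band_areas_shrink_monotonically_with_expansion_distance(self, default_dataset):
        islets = [IsletAnnotation(t.islet_id, t.polygon) for t in default_dataset.islets_truth]
        prev = None
        for d in (10.0, 6.0, 3.0):
            params = AnalysisParams(expansion_distance=d, raster_resolution=d / 20.0)
            areas = {b.islet_id: b.area for b in expand_islets(islets, params)}
            if prev is not None:
                assert all(areas[k] <= prev[k] + 1e-9 for k in areas)
            prev = areas

    def test_bands_are_pairwise_disjoint_and_exclude_islets(self, default_dataset):
        islets = [IsletAnnotation(t.islet_id, t.polygon) for t in default_dataset.islets_truth]
        bands = expand_islets(islets, AnalysisParams())
        union_islets = shapely.unary_union([i.polygon for i in islets])
        for b in bands:
            assert b.region.intersection(union_islets).area <= 1e-6
        for i, a in enumerate(bands):
            for b in bands[i + 1 :]:
                assert a.region.intersection(b.region).area <= 1e-6


class TestAssignCells:
    def setup_method(self):
        self.islets = [circle(0, 0, 20)]
        self.bands = expand_islets(self.islets, AnalysisParams())

    @pytest.mark.parametrize(
        "xy, region, islet_id",
        [
            ((0.0, 0.0), "intraislet", 1),  # centroid
            ((25.0, 0.0), "periphery", 1),  # 5 µm outside the boundary
            ((31.0, 0.0), "exocrine", 0),  # 11 µm outside
            ((20.0, 0.0), "intraislet", 1),  # on the boundary
        ],
    )
    def test_distance_rules(self, xy, region, islet_id):
        r, i = assign_cells(np.array([xy]), self.islets, self.bands)
        assert (r[0], i[0]) == (region, islet_id)

    def test_every_cell_gets_exactly_one_label(self, default_dataset):
        islets = [IsletAnnotation(t.islet_id, t.polygon) for t in default_dataset.islets_truth]
        bands = expand_islets(islets, AnalysisParams())
        xy = default_dataset.cells[["x_um", "y_um"]].to_numpy()
        region, islet_id = assign_cells(xy, islets, bands)
        assert len(region) == len(xy)
        counts = {lab: int((region == lab).sum()) for lab in set(region)}
        assert sum(counts.values()) == len(xy)
        assert ((region == "exocrine") == (islet_id == 0)).all()


class TestRasterOracle:
    def test_single_circle_area(self):
        oracle = raster_oracle([circle(0, 0, 20)], AnalysisParams(raster_resolution=0.25))
        assert oracle[1] == pytest.approx(ANNULUS_500PI, rel=0.01)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_oracle_and_polygon_bands_agree_on_random_sections(self, seed):
        ds = generate_section(
            SimulationConfig(n_islets=20, section_width=1600.0, section_height=1600.0, seed=seed)
        )
        islets = [IsletAnnotation(t.islet_id, t.polygon) for t in ds.islets_truth]
        params = AnalysisParams(raster_resolution=0.5)
        bands = expand_islets(islets, params)
        oracle = raster_oracle(islets, params)
        for b in bands:
            assert b.area == pytest.approx(oracle[b.islet_id], rel=0.02, abs=5.0)
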