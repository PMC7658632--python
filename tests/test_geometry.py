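import numpy as np
import pytest
import shapely
from shapely.geometry import Point, Polygon

from myelospat.geometry import (
    SQRT3,
    assign_cells_to_tiles,
    build_hex_grid,
    clip_cells_to_region,
    derive_invasive_margin,
    region_area,
)
from myelospat.io_model import RegionSet

from conftest import make_cells, square


class TestRegionArea:
    def test_unit_square_is_one_mm2(self, unit_square_regions):
        assert region_area(unit_square_regions, "tumor") == pytest.approx(1.0)

    def test_excluded_region_subtracted(self):
        regions = RegionSet(
            sample_id="S1",
            polygons=[(square(1000.0), "tumor"), (square(500.0), "excluded")],
        )
        assert region_area(regions, "tumor") == pytest.approx(0.75)

    def test_disjoint_squares_add(self):
        regions = RegionSet(
            sample_id="S1",
            polygons=[(square(1000.0), "tumor"), (square(1000.0, x0=5000.0), "tumor")],
        )
        assert region_area(regions, "tumor") == pytest.approx(2.0)

    def test_empty_class_errors(self, unit_square_regions):
        with pytest.raises(ValueError, match="normal"):
            region_area(unit_square_regions, "normal")


class TestInvasiveMargin:
    def test_circular_tumor_gives_annulus(self):
        circle = Point(0, 0).buffer(1000.0, quad_segs=256)
        regions = RegionSet(sample_id="S1", polygons=[(circle, "tumor")])
        band = derive_invasive_margin(regions, half_width=250.0)
        expected = np.pi * (1250.0**2 - 750.0**2) / 1e6  # mm²
        assert band.area / 1e6 == pytest.approx(expected, rel=1e-3)

    def test_zero_half_width_errors(self, unit_square_regions):
        with pytest.raises(ValueError):
            derive_invasive_margin(unit_square_regions, half_width=0.0)

    def test_degenerate_tumor_rejected(self):
        line = Polygon([(0, 0), (100, 0), (100, 0), (0, 0)])
        with pytest.raises(ValueError, match="valid"):
            RegionSet(sample_id="S1", polygons=[(line, "tumor")])

    def test_square_band_matches_raster_oracle(self):
        """Band area agrees with an independent rasterized estimate within 1%."""
        regions = RegionSet(sample_id="S1", polygons=[(square(2000.0), "tumor")])
        band = derive_invasive_margin(regions, half_width=250.0)
        # rasterize a generous window at 2 µm pitch and count covered pixels
        step = 2.0
        ax = np.arange(-300.0, 2300.0, step) + step / 2
        gx, gy = np.meshgrid(ax, ax)
        covered = shapely.contains_xy(band, gx.ravel(), gy.ravel())
        raster_area = covered.sum() * step**2
        assert band.area == pytest.approx(raster_area, rel=0.01)

    def test_band_area_monotone_in_half_width(self):
        tumor = Polygon([(0, 0), (2000, 100), (2400, 1800), (900, 2400), (-100, 1200)])
        regions = RegionSet(sample_id="S1", polygons=[(tumor, "tumor")])
        areas = [
            derive_invasive_margin(regions, half_width=h).area
            for h in (50.0, 150.0, 250.0, 400.0)
        ]
        assert np.all(np.diff(areas) > 0)

    def test_band_clipped_to_annotated_tissue(self):
        # normal tissue annotated only on the right: the left outer half is cut
        tumor = square(1000.0)
        normal = Polygon([(1000, 0), (2000, 0), (2000, 1000), (1000, 1000)])
        regions = RegionSet(sample_id="S1", polygons=[(tumor, "tumor"), (normal, "normal")])
        band = derive_invasive_margin(regions, half_width=250.0)
        unclipped = RegionSet(sample_id="S2", polygons=[(tumor, "tumor")])
        full = derive_invasive_margin(unclipped, half_width=250.0)
        assert band.area < full.area


class TestHexGrid:
    def test_full_hex_area_closed_form(self, unit_square_regions):
        grid = build_hex_grid(unit_square_regions, diagonal=250.0)
        # (3√3/2)·R² with R = 125 µm
        assert grid.full_hex_area_mm2 * 1e6 == pytest.approx(1.5 * SQRT3 * 125.0**2)
        assert grid.full_hex_area_mm2 == pytest.approx(0.0405949, rel=1e-5)

    def test_interior_tile_keeps_full_area(self):
        regions = RegionSet(sample_id="S1", polygons=[(square(5000.0), "tumor")])
        grid = build_hex_grid(regions, diagonal=250.0)
        assert grid.clipped_area_mm2.max() == pytest.approx(grid.full_hex_area_mm2)

    def test_clipped_areas_bounded_by_roi(self, unit_square_regions):
        grid = build_hex_grid(unit_square_regions, diagonal=250.0)
        assert grid.n_tiles > 0
        assert (grid.clipped_area_mm2 <= grid.full_hex_area_mm2 + 1e-12).all()
        assert grid.clipped_area_mm2.sum() <= region_area(unit_square_regions, "tumor")

    def test_tiny_roi_yields_empty_grid_with_warning(self):
        regions = RegionSet(sample_id="S1", polygons=[(square(50.0), "tumor")])
        with pytest.warns(UserWarning, match="empty grid"):
            grid = build_hex_grid(regions, diagonal=250.0)
        assert grid.n_tiles == 0

    def test_invalid_diagonal_errors(self, unit_square_regions):
        with pytest.raises(ValueError):
            build_hex_grid(unit_square_regions, diagonal=0.0)


class TestTileAssignment:
    def test_cell_at_tile_center_counted_there(self):
        regions = RegionSet(sample_id="S1", polygons=[(square(3000.0), "tumor")])
        grid = build_hex_grid(regions, diagonal=250.0)
        tile = grid.n_tiles // 2
        cells = make_cells("S1", grid.centers[[tile]], "ARG1")
        counts, dropped = assign_cells_to_tiles(cells, grid, phenotypes=["ARG1"])
        assert counts.loc[tile, "ARG1"] == 1
        assert counts["ARG1"].sum() == 1 and dropped["ARG1"] == 0

    def test_shared_edge_goes_to_lower_tile_index(self):
        regions = RegionSet(sample_id="S1", polygons=[(square(3000.0), "tumor")])
        grid = build_hex_grid(regions, diagonal=250.0)
        # midpoint of two adjacent centers lies exactly on their shared edge
        i = grid.n_tiles // 2
        d2 = np.sum((grid.centers - grid.centers[i]) ** 2, axis=1)
        j = int(np.argsort(d2)[1])
        mid = (grid.centers[i] + grid.centers[j]) / 2.0
        assigned = grid.assign(mid[None, :])
        assert assigned[0] == min(i, j)

    def test_conservation_of_random_points(self, rng):
        regions = RegionSet(sample_id="S1", polygons=[(square(2000.0), "tumor")])
        grid = build_hex_grid(regions, diagonal=250.0)
        pts = rng.uniform(0, 2000, size=(10_000, 2))
        cells = make_cells("S1", pts, "FOXP3")
        counts, dropped = assign_cells_to_tiles(cells, grid, phenotypes=["FOXP3"])
        assert counts["FOXP3"].sum() + dropped["FOXP3"] == 10_000

    def test_assignment_matches_nearest_center_oracle(self, rng):
        """Tile assignment equals a brute-force nearest-lattice-center search."""
        regions = RegionSet(sample_id="S1", polygons=[(square(1500.0), "tumor")])
        grid = build_hex_grid(regions, diagonal=250.0)
        pts = rng.uniform(-100, 1600, size=(2000, 2))
        assigned = grid.assign(pts)

        # independent oracle: enumerate a generous axial window and pick the
        # nearest center by exhaustive search
        R = grid.circumradius
        qs = np.arange(grid.axial[:, 0].min() - 3, grid.axial[:, 0].max() + 4)
        rs = np.arange(grid.axial[:, 1].min() - 3, grid.axial[:, 1].max() + 4)
        qq, rr = np.meshgrid(qs, rs)
        qq, rr = qq.ravel(), rr.ravel()
        centers = np.stack(
            [SQRT3 * R * (qq + rr / 2.0), 1.5 * R * rr], axis=1
        ) + grid.origin
        retained = {tuple(a): i for i, a in enumerate(grid.axial)}
        lattice_index = np.array(
            [retained.get((q, r), -1) for q, r in zip(qq, rr)], dtype=int
        )
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        oracle = lattice_index[np.argmin(d2, axis=1)]
        assert np.array_equal(assigned, oracle)

    def test_clip_cells_to_region_keeps_boundary(self):
        roi = square(1000.0)
        pts = np.array([[500.0, 500.0], [0.0, 500.0], [1500.0, 500.0]])
        cells = make_cells("S1", pts, "ARG1")
        clipped = clip_cells_to_region(cells, roi)
        assert len(clipped) == 2
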