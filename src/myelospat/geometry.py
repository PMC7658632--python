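"""Polygon algebra for annotated tissue regions.

Provides effective ROI areas, the invasive-margin band around the tumor
boundary, the hexagonal tessellation used for spatial overlap analysis, and
point-to-tile assignment.

Hexagon conventions: tiles are pointy-top regular hexagons whose long
(vertex-to-vertex) diagonal is the configured ``diagonal`` (so circumradius
R = diagonal / 2).  The grid is anchored at the lower-left corner of the
ROI bounding box; a tile is retained when its intersection with the tumor
ROI covers at least ``min_coverage`` of the full hexagon area, and densities
downstream are computed over the clipped (intersection) area so that edge
tiles are not inflated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon, mapping
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.prepared import prep

from .io_model import UM2_PER_MM2, CellTable, RegionClass, RegionSet

SQRT3 = np.sqrt(3.0)

# axial offsets of a lattice cell and its six neighbors, used for exact
# nearest-center assignment with a deterministic edge tie-break
_NEIGHBORHOOD = np.array(
    [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)], dtype=np.int64
)


def region_area(regions: RegionSet, region_class: str) -> float:
    """Effective area (mm²) of one region class, excluded regions subtracted."""
    geom = regions.class_union(region_class)
    return geom.area / UM2_PER_MM2


def derive_invasive_margin(regions: RegionSet, half_width: float = 250.0) -> BaseGeometry:
    """Derive the invasive-margin band straddling the tumor boundary.

    The band is (tumor ⊕ half_width) minus (tumor ⊖ half_width): a strip
    ``half_width`` µm wide on each side of the annotated tumor boundary.
    Where normal tissue is annotated the band is clipped to annotated tissue
    (tumor ∪ normal); excluded regions are always subtracted.  The result is
    stored on ``regions.invasive_margin`` and returned.
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    tumor = regions.class_union(RegionClass.TUMOR.value, subtract_excluded=False)
    if tumor.area == 0:
        raise ValueError(f"sample {regions.sample_id!r}: degenerate tumor polygon (area 0)")
    band = tumor.buffer(half_width).difference(tumor.buffer(-half_width))
    if regions.has_class(RegionClass.NORMAL.value):
        tissue = unary_union(
            [tumor, regions.class_union(RegionClass.NORMAL.value, subtract_excluded=False)]
        )
        band = band.intersection(tissue)
    excluded = [g for g, c in regions.polygons if c == RegionClass.EXCLUDED.value]
    if excluded:
        band = band.difference(unary_union(excluded))
    regions.invasive_margin = band
    return band


@dataclass
class HexGrid:
    """Hexagonal tessellation of a tumor ROI.

    ``centers`` are tile centers (µm), ``axial`` the integer axial lattice
    coordinates of each retained tile, and ``clipped_area_mm2`` the area of
    each tile's intersection with the ROI.  Tiles are indexed 0..N−1 in
    row-major (r, q) lattice order.
    """

    origin: np.ndarray  # (2,) anchor, µm
    circumradius: float  # µm
    centers: np.ndarray  # (N, 2) µm
    axial: np.ndarray  # (N, 2) int (q, r)
    polygons: list[Polygon]
    clipped_area_mm2: np.ndarray  # (N,)

    @property
    def n_tiles(self) -> int:
        return len(self.polygons)

    @property
    def full_hex_area_mm2(self) -> float:
        return 1.5 * SQRT3 * self.circumradius**2 / UM2_PER_MM2

    def __post_init__(self) -> None:
        if self.n_tiles:
            qs, rs = self.axial[:, 0], self.axial[:, 1]
            self._qmin, self._rmin = int(qs.min()), int(rs.min())
            self._index_map = -np.ones(
                (int(rs.max()) - self._rmin + 1, int(qs.max()) - self._qmin + 1),
                dtype=np.int64,
            )
            self._index_map[rs - self._rmin, qs - self._qmin] = np.arange(self.n_tiles)
        else:
            self._qmin = self._rmin = 0
            self._index_map = -np.ones((1, 1), dtype=np.int64)

    def _center_of(self, q, r):
        x = SQRT3 * self.circumradius * (np.asarray(q) + np.asarray(r) / 2.0)
        y = 1.5 * self.circumradius * np.asarray(r)
        return np.stack([x, y], axis=-1) + self.origin

    def _lookup(self, q: np.ndarray, r: np.ndarray) -> np.ndarray:
        qi = q - self._qmin
        ri = r - self._rmin
        ok = (
            (qi >= 0)
            & (qi < self._index_map.shape[1])
            & (ri >= 0)
            & (ri < self._index_map.shape[0])
        )
        out = -np.ones(q.shape, dtype=np.int64)
        out[ok] = self._index_map[ri[ok], qi[ok]]
        return out

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Map points (n, 2) to retained-tile indices (−1 for dropped tiles).

        Each point goes to the tile with the nearest center (the hexagons are
        the Voronoi cells of their centers, so this is exact containment).
        A point exactly equidistant between centers goes to the retained tile
        with the lower index; retained tiles win ties against dropped ones.
        """
        points = np.asarray(points, dtype=float)
        if points.size == 0:
            return np.zeros(0, dtype=np.int64)
        R = self.circumradius
        px = points[:, 0] - self.origin[0]
        py = points[:, 1] - self.origin[1]
        qf = (SQRT3 / 3.0 * px - py / 3.0) / R
        rf = (2.0 / 3.0 * py) / R
        q0, r0 = _cube_round(qf, rf)
        # evaluate the rounded cell and its six neighbors for an exact,
        # deterministically tie-broken nearest-center decision
        qc = q0[:, None] + _NEIGHBORHOOD[:, 0]
        rc = r0[:, None] + _NEIGHBORHOOD[:, 1]
        centers = self._center_of(qc, rc)
        d2 = np.sum((centers - points[:, None, :]) ** 2, axis=-1)
        idx = self._lookup(qc, rc)
        dmin = d2.min(axis=1)
        tied = d2 <= dmin[:, None] + 1e-9
        sentinel = self.n_tiles + 1
        candidate = np.where(tied & (idx >= 0), idx, sentinel).min(axis=1)
        # nearest center belongs to a dropped lattice cell and no retained
        # tile ties with it -> the point is dropped
        nearest_retained = np.where(tied, np.where(idx >= 0, 0, 1), 2).min(axis=1) == 0
        return np.where(nearest_retained, candidate, -1)

    def to_geojson(self, path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {
                    "tile_index": i,
                    "clipped_area_mm2": float(self.clipped_area_mm2[i]),
                },
                "geometry": mapping(self.polygons[i]),
            }
            for i in range(self.n_tiles)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def _cube_round(qf: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xf, zf = qf, rf
    yf = -xf - zf
    x, y, z = np.rint(xf), np.rint(yf), np.rint(zf)
    dx, dy, dz = np.abs(x - xf), np.abs(y - yf), np.abs(z - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    x = np.where(fix_x, -y - z, x)
    z = np.where(fix_z, -x - y, z)
    return x.astype(np.int64), z.astype(np.int64)


def _hexagon(center: np.ndarray, R: float) -> Polygon:
    ang = np.deg2rad(90.0 + 60.0 * np.arange(6))
    verts = center + R * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    return Polygon(verts)


def build_hex_grid(
    regions: RegionSet | BaseGeometry,
    diagonal: float = 250.0,
    min_coverage: float = 0.5,
) -> HexGrid:
    """Tessellate the tumor ROI with pointy-top hexagons.

    ``regions`` may be a :class:`RegionSet` (its tumor class union, excluded
    regions subtracted, is used) or a ready-made ROI geometry.  Tiles whose
    intersection with the ROI covers less than ``min_coverage`` of the full
    hexagon area are dropped; retained tiles store their clipped area.
    """
    if diagonal <= 0:
        raise ValueError("diagonal must be > 0")
    roi = (
        regions.class_union(RegionClass.TUMOR.value)
        if isinstance(regions, RegionSet)
        else regions
    )
    if roi.is_empty or roi.area == 0:
        raise ValueError("tumor ROI is empty")
    R = diagonal / 2.0
    minx, miny, maxx, maxy = roi.bounds
    origin = np.array([minx, miny])
    full_area = 1.5 * SQRT3 * R**2

    r_lo = int(np.floor((-R) / (1.5 * R))) - 1
    r_hi = int(np.ceil((maxy - miny + R) / (1.5 * R))) + 1
    prepared = prep(roi)

    axial, centers, polys, areas = [], [], [], []
    for r in range(r_lo, r_hi + 1):
        cy = 1.5 * R * r
        q_lo = int(np.floor(-R / (SQRT3 * R) - r / 2.0)) - 2
        q_hi = int(np.ceil((maxx - minx + R) / (SQRT3 * R) - r / 2.0)) + 2
        for q in range(q_lo, q_hi + 1):
            center = origin + np.array([SQRT3 * R * (q + r / 2.0), cy])
            if not (
                minx - R <= center[0] <= maxx + R and miny - R <= center[1] <= maxy + R
            ):
                continue
            hexagon = _hexagon(center, R)
            if prepared.covers(hexagon):
                clipped = full_area
            elif prepared.intersects(hexagon):
                clipped = hexagon.intersection(roi).area
            else:
                continue
            if clipped >= min_coverage * full_area:
                axial.append((q, r))
                centers.append(center)
                polys.append(hexagon)
                areas.append(clipped)

    if not polys:
        warnings.warn("ROI smaller than one retained tile; returning an empty grid")
        return HexGrid(
            origin=origin,
            circumradius=R,
            centers=np.zeros((0, 2)),
            axial=np.zeros((0, 2), dtype=np.int64),
            polygons=[],
            clipped_area_mm2=np.zeros(0),
        )
    return HexGrid(
        origin=origin,
        circumradius=R,
        centers=np.asarray(centers, dtype=float),
        axial=np.asarray(axial, dtype=np.int64),
        polygons=polys,
        clipped_area_mm2=np.asarray(areas) / UM2_PER_MM2,
    )


def assign_cells_to_tiles(
    cells: CellTable, grid: HexGrid, phenotypes: list[str] | None = None
) -> tuple["pd.DataFrame", dict[str, int]]:
    """Count cells per retained tile and phenotype.

    Cells must already be clipped to the tumor ROI.  Each cell inside a
    retained tile is counted in exactly one tile; cells falling in dropped
    (<``min_coverage``) tiles are counted nowhere and reported in the second
    return value.  Requesting the ``"CD8"`` phenotype counts the union of
    aggregate and Ki67-split cytotoxic labels.
    """
    import pandas as pd

    if phenotypes is None:
        phenotypes = sorted(set(cells.data["phenotype"]))
    counts = np.zeros((grid.n_tiles, len(phenotypes)), dtype=np.int64)
    dropped: dict[str, int] = {}
    for j, ph in enumerate(phenotypes):
        pts = cells.points(ph)
        if len(pts) == 0:
            dropped[ph] = 0
            continue
        idx = grid.assign(pts)
        inside = idx >= 0
        np.add.at(counts[:, j], idx[inside], 1)
        dropped[ph] = int(np.count_nonzero(~inside))
    frame = pd.DataFrame(counts, columns=phenotypes)
    frame.index.name = "tile_index"
    return frame, dropped


def clip_cells_to_region(cells: CellTable, roi: BaseGeometry) -> CellTable:
    """Return a CellTable containing only the cells covered by ``roi``."""
    import shapely

    xy = cells.data[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy) == 0:
        return cells
    inside = shapely.contains_xy(roi, xy[:, 0], xy[:, 1]) | shapely.intersects_xy(
        roi.boundary, xy[:, 0], xy[:, 1]
    )
    return CellTable(sample_id=cells.sample_id, data=cells.data.loc[inside].reset_index(drop=True))
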