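"""Spatial statistics of myeloid and T-cell organization.

The two headline quantities are:

GAD / GAD_norm
    The global average distance (GAD) of a sample is the mean, over CD8+
    T cells in the tumor ROI, of the Euclidean distance to the nearest
    myeloid cell.  To remove the trivial dependence on myeloid abundance it
    is normalized by the Clark–Evans expected nearest-neighbor distance
    under complete spatial randomness, 0.5·√(A/n), where n is the myeloid
    cell count and A the tumor ROI area (converted to µm²):

        GAD_norm = GAD / (0.5·√(A/n))

    GAD_norm ≈ 1 for randomly placed myeloid cells, > 1 when myeloid cells
    cluster away from T cells, < 1 when the two populations co-localize.

MTO (myeloid–T-cell overlap)
    The tumor ROI is tessellated with hexagonal tiles; a tile is "hot" for
    cell type j when its tile density d_ij strictly exceeds D_j, the
    cohort-wide median tumor density of that type.  MTO is the fraction of
    CD8-hot tiles that are also myeloid-hot:

        MTO = Σ_i h_ij·h_ik / Σ_i h_ij      (j = CD8, k = myeloid type)

Samples are stratified into four categories by (CD8 tumor density, MTO)
relative to the cohort medians: low/low → 1, low/high → 2, high/high → 3,
high/low → 4.  Values at or below a median count as "low".
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from scipy.spatial import cKDTree

from .geometry import HexGrid, assign_cells_to_tiles, clip_cells_to_region, region_area
from .io_model import (
    UM2_PER_MM2,
    CellTable,
    Phenotype,
    RegionClass,
    RegionSet,
)


@dataclass
class DistanceResult:
    """Per-sample nearest-myeloid distance summary for one myeloid type."""

    sample_id: str
    myeloid_type: str
    gad: float  # µm; NaN when undefined
    n: int  # myeloid cells in the tumor ROI
    area_mm2: float
    gad_norm: float  # dimensionless; NaN when undefined

    @property
    def defined(self) -> bool:
        return np.isfinite(self.gad_norm)


@dataclass
class CohortThresholds:
    """Cohort-wide medians used for hot-tile labeling and stratification.

    ``density_medians`` maps cell type → median of sample-level tumor
    densities (cells/mm²); medians are taken only over samples where the
    quantity is defined.
    """

    density_medians: dict[str, float]
    cd8_density_median: float
    mto_medians: dict[str, float]


@dataclass
class OverlapResult:
    """Hot-tile flags and the MTO score for one sample and myeloid type."""

    sample_id: str
    myeloid_type: str
    hot: pd.DataFrame  # tiles × cell types, boolean
    mto: float  # NaN when the sample has no CD8-hot tile

    @property
    def defined(self) -> bool:
        return np.isfinite(self.mto)


#: category lookup keyed by (cd8_level, mto_level)
_CATEGORY = {
    ("low", "low"): 1,
    ("low", "high"): 2,
    ("high", "high"): 3,
    ("high", "low"): 4,
}


@dataclass
class StratumAssignment:
    sample_id: str
    myeloid_type: str
    category: int
    cd8_level: str
    mto_level: str


def compute_density(
    cells: CellTable, regions: RegionSet, region_class: str, phenotype: str
) -> float:
    """Density (cells/mm²) of one phenotype inside one region class.

    Only cells covered by the effective region (excluded areas subtracted)
    are counted.
    """
    geom = regions.class_union(region_class)
    area = geom.area / UM2_PER_MM2
    if area <= 0:
        raise ValueError(
            f"sample {regions.sample_id!r}: zero effective {region_class} area"
        )
    pts = cells.points(phenotype)
    if len(pts) == 0:
        return 0.0
    inside = shapely.contains_xy(geom, pts[:, 0], pts[:, 1]) | shapely.intersects_xy(
        geom.boundary, pts[:, 0], pts[:, 1]
    )
    return float(np.count_nonzero(inside)) / area


def compute_gad(cd8_points: np.ndarray, myeloid_points: np.ndarray) -> float:
    """Mean distance (µm) from each CD8 cell to its nearest myeloid cell.

    Returns NaN when either side is empty (the sample is then flagged
    downstream rather than contributing a degenerate value).
    """
    cd8_points = np.asarray(cd8_points, dtype=float).reshape(-1, 2)
    myeloid_points = np.asarray(myeloid_points, dtype=float).reshape(-1, 2)
    if len(cd8_points) == 0 or len(myeloid_points) == 0:
        return float("nan")
    dists, _ = cKDTree(myeloid_points).query(cd8_points, k=1)
    return float(np.mean(dists))


def normalize_gad(gad: float, n: int, area_mm2: float) -> float:
    """Normalize GAD by the expected CSR nearest-neighbor distance 0.5·√(A/n)."""
    if n == 0 or not np.isfinite(gad):
        return float("nan")
    if area_mm2 <= 0:
        raise ValueError("area must be > 0")
    expected = 0.5 * sqrt(area_mm2 * UM2_PER_MM2 / n)
    return gad / expected


def sample_distance_result(
    cells: CellTable, regions: RegionSet, myeloid_type: str
) -> DistanceResult:
    """GAD and GAD_norm for one sample and myeloid type, in the tumor ROI."""
    roi = regions.class_union(RegionClass.TUMOR.value)
    clipped = clip_cells_to_region(cells, roi)
    cd8 = clipped.points(Phenotype.CD8.value)
    myeloid = clipped.points(myeloid_type)
    area = roi.area / UM2_PER_MM2
    gad = compute_gad(cd8, myeloid)
    return DistanceResult(
        sample_id=cells.sample_id,
        myeloid_type=myeloid_type,
        gad=gad,
        n=len(myeloid),
        area_mm2=area,
        gad_norm=normalize_gad(gad, len(myeloid), area),
    )


def cohort_thresholds(
    densities: pd.DataFrame, mto: pd.DataFrame | None = None
) -> CohortThresholds:
    """Cohort medians of sample-level tumor densities (and MTO, if given).

    ``densities`` is samples × cell types (cells/mm²); ``mto`` is samples ×
    myeloid types.  Medians skip missing values; a quantity missing for
    every sample raises.
    """
    if len(densities) < 2:
        raise ValueError("need at least 2 samples to form cohort thresholds")
    medians: dict[str, float] = {}
    for col in densities.columns:
        vals = densities[col].dropna()
        if vals.empty:
            raise ValueError(f"density {col!r} undefined for every sample")
        medians[col] = float(vals.median())
    cd8_median = medians.get(Phenotype.CD8.value, float("nan"))
    mto_medians: dict[str, float] = {}
    if mto is not None:
        for col in mto.columns:
            vals = mto[col].dropna()
            if vals.empty:
                raise ValueError(f"MTO for {col!r} undefined for every sample")
            mto_medians[col] = float(vals.median())
    return CohortThresholds(
        density_medians=medians, cd8_density_median=cd8_median, mto_medians=mto_medians
    )


def tile_densities(
    cells: CellTable, grid: HexGrid, cell_types: list[str]
) -> pd.DataFrame:
    """Per-tile densities d_ij (cells/mm² over the clipped tile area)."""
    counts, _ = assign_cells_to_tiles(cells, grid, phenotypes=cell_types)
    return counts.div(pd.Series(grid.clipped_area_mm2, index=counts.index), axis=0)


def label_hot_tiles(
    densities: pd.DataFrame, thresholds: CohortThresholds
) -> pd.DataFrame:
    """Flag tile i hot for type j iff d_ij strictly exceeds the cohort D_j."""
    missing = [c for c in densities.columns if c not in thresholds.density_medians]
    if missing:
        raise ValueError(f"no cohort density median for cell type(s) {missing}")
    ref = pd.Series({c: thresholds.density_medians[c] for c in densities.columns})
    return densities.gt(ref, axis=1)


def compute_mto(hot: pd.DataFrame, j: str = Phenotype.CD8.value, k: str = "") -> float:
    """Fraction of j-hot tiles that are also k-hot (Myeloid–T-cell Overlap).

    Returns NaN when the sample has no j-hot tile; such samples are
    excluded from cohort medians and contrasts downstream.
    """
    for col in (j, k):
        if col not in hot.columns:
            raise ValueError(f"hot-flag table lacks cell type {col!r}")
    hj = hot[j].to_numpy(dtype=bool)
    hk = hot[k].to_numpy(dtype=bool)
    denom = int(hj.sum())
    if denom == 0:
        return float("nan")
    return float(np.count_nonzero(hj & hk)) / denom


def sample_overlap_result(
    cells: CellTable,
    regions: RegionSet,
    grid: HexGrid,
    thresholds: CohortThresholds,
    myeloid_type: str,
) -> OverlapResult:
    """Hot-tile labels and MTO for one sample and myeloid type."""
    roi = regions.class_union(RegionClass.TUMOR.value)
    clipped = clip_cells_to_region(cells, roi)
    dens = tile_densities(clipped, grid, [Phenotype.CD8.value, myeloid_type])
    hot = label_hot_tiles(dens, thresholds)
    mto = compute_mto(hot, j=Phenotype.CD8.value, k=myeloid_type)
    return OverlapResult(
        sample_id=cells.sample_id, myeloid_type=myeloid_type, hot=hot, mto=mto
    )


def stratify_sample(
    sample_id: str,
    myeloid_type: str,
    cd8_density: float,
    mto: float,
    thresholds: CohortThresholds,
) -> StratumAssignment | None:
    """Assign a sample to one of the four (CD8 density, MTO) categories.

    A level is "high" iff the value strictly exceeds the cohort median
    (ties map to "low", so category counts are reproducible).  Samples with
    undefined MTO get no assignment and are reported by the caller.
    """
    if not np.isfinite(mto):
        return None
    mto_median = thresholds.mto_medians[myeloid_type]
    cd8_level = "high" if cd8_density > thresholds.cd8_density_median else "low"
    mto_level = "high" if mto > mto_median else "low"
    return StratumAssignment(
        sample_id=sample_id,
        myeloid_type=myeloid_type,
        category=_CATEGORY[(cd8_level, mto_level)],
        cd8_level=cd8_level,
        mto_level=mto_level,
    )


def cohort_statistics(
    table: pd.DataFrame,
    group_col: str | None = None,
    value_cols: list[str] | None = None,
) -> dict:
    """Cohort-level comparison statistics.

    Returns two-sided Mann–Whitney U p-values for two-group contrasts of
    each value column (e.g. MSI vs MSS), the Pearson correlation matrix
    across value columns, and — when Ki67-split CD8 densities are present —
    the proliferating fraction of CD8 cells as a derived column.
    """
    if value_cols is None:
        value_cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    if len(table) < 3:
        raise ValueError("need at least 3 samples")
    out: dict = {"mann_whitney": {}, "warnings": []}

    pos, neg = Phenotype.CD8_KI67POS.value, Phenotype.CD8_KI67NEG.value
    if pos in table.columns and neg in table.columns:
        total = table[pos] + table[neg]
        table = table.assign(cd8_ki67_fraction=table[pos] / total.where(total > 0))
        value_cols = list(value_cols) + ["cd8_ki67_fraction"]

    if group_col is not None:
        groups = [g for _, g in table.groupby(group_col, sort=True)]
        if len(groups) != 2:
            raise ValueError("group contrasts require exactly 2 groups")
        for col in value_cols:
            a = groups[0][col].dropna()
            b = groups[1][col].dropna()
            if len(a) < 1 or len(b) < 1:
                out["warnings"].append(f"contrast for {col!r} skipped: empty group")
                continue
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            out["mann_whitney"][col] = {"U": float(stat), "p": float(p)}

    out["pearson"] = table[value_cols].corr(method="pearson")
    return out
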