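"""Domain types and file I/O for the spatial cohort pipeline.

Coordinates are planar, in micrometres (µm), with y increasing downward
(image convention).  Areas are always reported in mm² (1 mm² = 1e6 µm²) and
densities in cells/mm², matching scanner exports and the units used
throughout digital-pathology studies.

Cell tables follow the shape of a HALO object-data export: one row per
detected cell with a sample id, x/y centroid coordinates and a phenotype
label from a closed vocabulary.  Region annotations are GeoJSON
FeatureCollections of classed polygons (tumor / normal / excluded).
Expression matrices are genes × samples TSV on a log2 RPKM scale.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

UM2_PER_MM2 = 1.0e6

CELL_CSV_COLUMNS = ["sample_id", "x_um", "y_um", "phenotype"]


class Phenotype(str, enum.Enum):
    """Closed vocabulary of cell phenotypes.

    ``CD8`` denotes cytotoxic T cells with unresolved proliferation status;
    when Ki67 status is available the split labels are used instead and the
    CD8 compartment is their union.
    """

    CD8 = "CD8"
    CD8_KI67POS = "CD8_Ki67pos"
    CD8_KI67NEG = "CD8_Ki67neg"
    CD11B_CD14 = "CD11b_CD14"
    CD11B_CD15 = "CD11b_CD15"
    ARG1 = "ARG1"
    FOXP3 = "FOXP3"
    TUMOR_KI67POS = "TUMOR_Ki67pos"


PHENOTYPE_VALUES = frozenset(p.value for p in Phenotype)

#: Labels whose union forms the total cytotoxic CD8 compartment.
CD8_COMPARTMENT = frozenset(
    {Phenotype.CD8.value, Phenotype.CD8_KI67POS.value, Phenotype.CD8_KI67NEG.value}
)

MYELOID_TYPES = (Phenotype.CD11B_CD14.value, Phenotype.CD11B_CD15.value)


class RegionClass(str, enum.Enum):
    TUMOR = "tumor"
    NORMAL = "normal"
    EXCLUDED = "excluded"


REGION_CLASS_VALUES = frozenset(r.value for r in RegionClass)


@dataclass
class CellTable:
    """Per-sample cell centroids with phenotype labels.

    ``data`` holds columns ``x_um``, ``y_um``, ``phenotype``; coordinates
    must be finite and phenotypes must come from :class:`Phenotype`.
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("x_um", "y_um", "phenotype") if c not in self.data.columns]
        if missing:
            raise ValueError(f"CellTable missing columns: {missing}")
        xy = self.data[["x_um", "y_um"]].to_numpy(dtype=float)
        if xy.size and not np.isfinite(xy).all():
            raise ValueError(f"non-finite coordinates in sample {self.sample_id!r}")
        bad = sorted(set(self.data["phenotype"]) - PHENOTYPE_VALUES)
        if bad:
            raise ValueError(
                f"unknown phenotype label(s) {bad} in sample {self.sample_id!r}; "
                f"allowed: {sorted(PHENOTYPE_VALUES)}"
            )
        labels = set(self.data["phenotype"])
        if Phenotype.CD8.value in labels and labels & {
            Phenotype.CD8_KI67POS.value,
            Phenotype.CD8_KI67NEG.value,
        }:
            raise ValueError(
                f"sample {self.sample_id!r} mixes the aggregate 'CD8' label with "
                "Ki67-split CD8 labels; use one representation to avoid double counting"
            )
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def points(self, phenotype: str) -> np.ndarray:
        """Return an (n, 2) array of coordinates for one phenotype.

        Requesting ``"CD8"`` returns the union of the aggregate and the
        Ki67-split cytotoxic T-cell labels.
        """
        if phenotype == Phenotype.CD8.value:
            mask = self.data["phenotype"].isin(CD8_COMPARTMENT)
        else:
            if phenotype not in PHENOTYPE_VALUES:
                raise ValueError(f"unknown phenotype {phenotype!r}")
            mask = self.data["phenotype"] == phenotype
        return self.data.loc[mask, ["x_um", "y_um"]].to_numpy(dtype=float)


@dataclass
class RegionSet:
    """Classed annotation polygons for one sample.

    ``polygons`` is a list of ``(geometry, region_class)`` pairs.  Excluded
    regions are subtracted from every class geometry before any area or
    density computation.  ``invasive_margin`` holds the derived band polygon
    once computed.
    """

    sample_id: str
    polygons: list[tuple[BaseGeometry, str]]
    invasive_margin: BaseGeometry | None = None

    def __post_init__(self) -> None:
        for i, (geom, cls) in enumerate(self.polygons):
            if cls not in REGION_CLASS_VALUES:
                raise ValueError(
                    f"region {i} of sample {self.sample_id!r}: unknown class {cls!r}"
                )
            if not geom.is_valid:
                raise ValueError(
                    f"region {i} ({cls}) of sample {self.sample_id!r} is not a valid polygon"
                )

    def class_union(self, region_class: str, subtract_excluded: bool = True) -> BaseGeometry:
        """Union of all polygons of one class, minus excluded regions."""
        from shapely.ops import unary_union

        geoms = [g for g, c in self.polygons if c == region_class]
        if not geoms:
            raise ValueError(
                f"sample {self.sample_id!r} has no region of class {region_class!r}"
            )
        union = unary_union(geoms)
        if subtract_excluded and region_class != RegionClass.EXCLUDED.value:
            excluded = [g for g, c in self.polygons if c == RegionClass.EXCLUDED.value]
            if excluded:
                union = union.difference(unary_union(excluded))
        return union

    def has_class(self, region_class: str) -> bool:
        return any(c == region_class for _, c in self.polygons)


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values on a log2 RPKM scale."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValueError(f"duplicate gene id(s): {dups[:10]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class RunConfig:
    """Tunable analysis parameters.

    hex_diagonal
        Long (vertex-to-vertex) diagonal of the hexagonal grid tiles, µm.
    margin_half_width
        Half-width of the invasive-margin band, µm (band straddles the tumor
        boundary by this much on each side).
    signature_cutoff_cd14 / signature_cutoff_cd15
        |R| thresholds used to derive distance signatures from per-gene
        Spearman correlations against GAD_CD14 / GAD_CD15.
    min_tile_coverage
        Fraction of the full hexagon area a tile must share with the tumor
        ROI to be retained in the grid.
    """

    hex_diagonal: float = 250.0
    margin_half_width: float = 250.0
    signature_cutoff_cd14: float = 0.4
    signature_cutoff_cd15: float = 0.3
    n_permutations: int = 10000
    rng_seed: int = 0
    min_tile_coverage: float = 0.5

    def __post_init__(self) -> None:
        if self.hex_diagonal <= 0 or self.margin_half_width <= 0:
            raise ValueError("lengths must be > 0")
        for cut in (self.signature_cutoff_cd14, self.signature_cutoff_cd15):
            if not 0 < cut < 1:
                raise ValueError("signature cutoffs must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.min_tile_coverage <= 1:
            raise ValueError("min_tile_coverage must lie in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class Cohort:
    """Bundle of per-sample cells and regions, plus optional expression."""

    cells: dict[str, CellTable]
    regions: dict[str, RegionSet]
    expression: ExpressionMatrix | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.cells)


# ---------------------------------------------------------------------------
# readers


def read_cells(path, errors: str = "raise") -> tuple[dict[str, CellTable], pd.DataFrame]:
    """Read a cell CSV (``sample_id,x_um,y_um,phenotype``) into CellTables.

    With ``errors="raise"`` any unknown phenotype aborts with an error
    listing the offending labels.  With ``errors="collect"`` offending rows
    are set aside and returned in the rejects frame (columns of the input
    plus ``reason``), so that rows in = rows accepted + rows rejected.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "phenotype": str})
    missing = [c for c in CELL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell CSV {path} missing column(s): {missing}")

    coords = df[["x_um", "y_um"]].apply(pd.to_numeric, errors="coerce")
    bad_coord = ~np.isfinite(coords.to_numpy()).all(axis=1)
    bad_pheno = ~df["phenotype"].isin(PHENOTYPE_VALUES)
    if errors == "raise":
        if bad_pheno.any():
            labels = sorted(df.loc[bad_pheno, "phenotype"].unique())
            raise ValueError(f"unknown phenotype label(s) in {path}: {labels}")
        if bad_coord.any():
            raise ValueError(f"non-finite coordinates in {path} (rows {list(df.index[bad_coord])[:5]})")
        rejects = df.iloc[0:0].assign(reason=pd.Series(dtype=str))
        accepted = df
    else:
        bad = bad_pheno | bad_coord
        reason = np.where(bad_pheno, "unknown phenotype", "non-finite coordinate")
        rejects = df.loc[bad].assign(reason=reason[bad.to_numpy()])
        accepted = df.loc[~bad]

    tables: dict[str, CellTable] = {}
    for sid, grp in accepted.groupby("sample_id", sort=True):
        sub = grp[["x_um", "y_um", "phenotype"]].copy()
        sub[["x_um", "y_um"]] = sub[["x_um", "y_um"]].astype(float)
        tables[str(sid)] = CellTable(sample_id=str(sid), data=sub.reset_index(drop=True))
    return tables, rejects


def write_cells(tables: dict[str, CellTable], path) -> None:
    frames = []
    for sid in sorted(tables):
        t = tables[sid]
        frames.append(t.data.assign(sample_id=sid)[CELL_CSV_COLUMNS])
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=CELL_CSV_COLUMNS)
    out.to_csv(path, index=False, float_format="%.6f")


def read_regions(path) -> dict[str, RegionSet]:
    """Read a GeoJSON FeatureCollection of classed region polygons.

    Each feature must carry ``region_class`` and ``sample_id`` properties.
    A malformed ring raises a parse error naming the feature.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    per_sample: dict[str, list[tuple[BaseGeometry, str]]] = {}
    for k, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        name = props.get("name", f"feature {k}")
        cls = props.get("region_class")
        sid = str(props.get("sample_id", ""))
        if cls not in REGION_CLASS_VALUES:
            raise ValueError(f"{path}: {name}: missing or unknown region_class {cls!r}")
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:  # noqa: BLE001 - surface feature name
            raise ValueError(f"{path}: {name}: cannot parse geometry ({exc})") from exc
        if not geom.is_valid or geom.is_empty:
            raise ValueError(f"{path}: {name}: malformed ring (invalid or empty polygon)")
        per_sample.setdefault(sid, []).append((geom, cls))
    return {
        sid: RegionSet(sample_id=sid, polygons=polys) for sid, polys in per_sample.items()
    }


def write_regions(regions: dict[str, RegionSet], path) -> None:
    features = []
    for sid in sorted(regions):
        rs = regions[sid]
        for k, (geom, cls) in enumerate(rs.polygons):
            features.append(
                {
                    "type": "Feature",
                    "properties": {"sample_id": sid, "region_class": cls, "name": f"{sid}/{cls}/{k}"},
                    "geometry": mapping(geom),
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_expression(path) -> ExpressionMatrix:
    """Read a genes × samples TSV (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return ExpressionMatrix(values=df.astype(float))


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


def read_inputs(cell_csv_path, regions_geojson_path, expression_tsv_path=None) -> Cohort:
    """Load and cross-validate a cohort from its on-disk representation.

    Samples present in the cell table but missing region annotations are
    reported in the cohort's ``warnings`` (they cannot enter any area-based
    statistic).
    """
    cells, _ = read_cells(cell_csv_path, errors="raise")
    regions = read_regions(regions_geojson_path)
    warnings = [
        f"sample {sid!r} has cells but no region annotations"
        for sid in sorted(set(cells) - set(regions))
    ]
    expr = read_expression(expression_tsv_path) if expression_tsv_path else None
    return Cohort(cells=cells, regions=regions, expression=expr, warnings=warnings)
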