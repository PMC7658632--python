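"""Synthetic cohorts with known spatial and transcriptional ground truth.

Because real cell coordinates from pathology studies are rarely deposited,
every pipeline stage is exercised against simulated cohorts whose ground
truth is recorded in a manifest:

* ROI polygons — a rectangle of configurable area, or a star-convex "blob".
* Point patterns per phenotype — complete spatial randomness (homogeneous
  Poisson), or a Thomas cluster process (Poisson parents, Poisson numbers
  of offspring displaced by an isotropic Gaussian).  The Thomas process is
  used because it has closed-form intensity and makes co-localization easy
  to plant: a configurable fraction of CD8 cluster parents is shared with
  the myeloid parents.
* Expression — a Gaussian copula couples planted genes to the ranks of the
  realized per-sample GAD_norm at a target Spearman ρ (exact in
  expectation, independent of marginals); null genes are independent.
  Values are mapped onto a plausible log2 RPKM scale.

Expected regimes (asserted in the manifest, reproduced by the pipeline):
CSR myeloid ⇒ GAD_norm ≈ 1; clustered myeloid with independent CD8 ⇒
GAD_norm > 1; shared cluster parents ⇒ GAD_norm < 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import Polygon

from .io_model import (
    UM2_PER_MM2,
    CellTable,
    Cohort,
    ExpressionMatrix,
    Phenotype,
    RegionClass,
    RegionSet,
)
from .spatial_metrics import sample_distance_result

#: default per-phenotype tumor-ROI intensities (cells/mm²), matching the
#: cohort medians reported for treatment-naive colorectal tumors
DEFAULT_INTENSITIES: dict[str, float] = {
    Phenotype.CD8.value: 76.64,
    Phenotype.CD11B_CD14.value: 35.32,
    Phenotype.CD11B_CD15.value: 122.12,
    Phenotype.FOXP3.value: 129.89,
    Phenotype.ARG1.value: 100.0,
    Phenotype.TUMOR_KI67POS.value: 500.0,
}


@dataclass
class PointPattern:
    """Spatial law of one phenotype: ``csr`` or ``thomas``.

    For a Thomas process the per-parent offspring mean is derived from the
    phenotype's target intensity (mean_offspring = intensity /
    parents_per_mm2), so changing the pattern never changes the expected
    cell count.
    """

    kind: str = "csr"  # "csr" | "thomas"
    parents_per_mm2: float = 5.0
    sigma_um: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("csr", "thomas"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.kind == "thomas" and (self.parents_per_mm2 <= 0 or self.sigma_um <= 0):
            raise ValueError("thomas pattern needs parents_per_mm2 > 0 and sigma_um > 0")


@dataclass
class SyntheticCohortConfig:
    """Ground-truth knobs of a synthetic cohort.

    ``co_cluster_fraction`` is the fraction of CD8 cluster parents shared
    with ``co_cluster_partner`` myeloid parents (both phenotypes must then
    follow a Thomas pattern).  ``planted_rho`` maps gene id → target
    Spearman correlation with the per-sample GAD_norm of ``gad_source``.
    """

    n_samples: int = 74
    roi_shape: str = "rectangle"  # "rectangle" | "blob"
    roi_area_mm2: float = 5.0
    intensities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    patterns: dict[str, PointPattern] = field(default_factory=dict)
    co_cluster_fraction: float = 0.0
    co_cluster_partner: str = Phenotype.CD11B_CD14.value
    cd8_ki67_fraction: float = 0.3
    n_genes: int = 200
    planted_rho: dict[str, float] = field(default_factory=dict)
    gad_source: str = Phenotype.CD11B_CD14.value
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_area_mm2 <= 0:
            raise ValueError("roi_area_mm2 must be > 0")
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError("intensities must be >= 0")
        if not 0 <= self.co_cluster_fraction <= 1:
            raise ValueError("co_cluster_fraction must lie in [0, 1]")
        if any(abs(r) >= 1 for r in self.planted_rho.values()):
            raise ValueError("planted Spearman correlations must satisfy |rho| < 1")

    def pattern_for(self, phenotype: str) -> PointPattern:
        return self.patterns.get(phenotype, PointPattern(kind="csr"))


@dataclass
class CohortBundle:
    cells: dict[str, CellTable]
    regions: dict[str, RegionSet]
    expression: ExpressionMatrix | None
    manifest: dict

    def as_cohort(self) -> Cohort:
        return Cohort(cells=self.cells, regions=self.regions, expression=self.expression)


def _make_roi(config: SyntheticCohortConfig, rng: np.random.Generator) -> Polygon:
    area_um2 = config.roi_area_mm2 * UM2_PER_MM2
    if config.roi_shape == "rectangle":
        side = math.sqrt(area_um2)
        return Polygon([(0, 0), (side, 0), (side, side), (0, side)])
    if config.roi_shape == "blob":
        # star-convex blob: smooth radial noise around a circle, rescaled
        # to the target area
        n_vert = 48
        theta = np.linspace(0, 2 * np.pi, n_vert, endpoint=False)
        k = np.arange(1, 4)
        amp = rng.normal(size=3) * np.array([0.15, 0.10, 0.05])
        phase = rng.uniform(0, 2 * np.pi, size=3)
        radial = 1.0 + (amp[None, :] * np.cos(theta[:, None] * k + phase)).sum(axis=1)
        radial = np.clip(radial, 0.4, None)
        base = math.sqrt(area_um2 / math.pi)
        poly = Polygon(
            np.stack([base * radial * np.cos(theta), base * radial * np.sin(theta)], axis=1)
        )
        scale = math.sqrt(area_um2 / poly.area)
        return shapely.affinity.scale(poly, xfact=scale, yfact=scale, origin=(0, 0))
    raise ValueError(f"unknown roi_shape {config.roi_shape!r}")


def _points_in_polygon(
    roi: Polygon, n: int, rng: np.random.Generator, max_iter: int = 200
) -> np.ndarray:
    """Uniform points inside a polygon via bounding-box rejection."""
    if n == 0:
        return np.zeros((0, 2))
    minx, miny, maxx, maxy = roi.bounds
    out: list[np.ndarray] = []
    got = 0
    frac = max(roi.area / ((maxx - minx) * (maxy - miny)), 1e-3)
    for _ in range(max_iter):
        m = int((n - got) / frac * 1.2) + 8
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(m, 2))
        keep = shapely.contains_xy(roi, cand[:, 0], cand[:, 1])
        sel = cand[keep]
        out.append(sel)
        got += len(sel)
        if got >= n:
            break
    pts = np.concatenate(out)
    if len(pts) < n:
        raise RuntimeError("rejection sampling failed to fill the polygon")
    return pts[:n]


def _thomas_parents(
    roi: Polygon, pattern: PointPattern, rng: np.random.Generator
) -> np.ndarray:
    """Parents on an extended window so clusters straddle the ROI edge."""
    pad = 4.0 * pattern.sigma_um
    minx, miny, maxx, maxy = roi.bounds
    ext_area_mm2 = ((maxx - minx) + 2 * pad) * ((maxy - miny) + 2 * pad) / UM2_PER_MM2
    n_par = rng.poisson(pattern.parents_per_mm2 * ext_area_mm2)
    return rng.uniform((minx - pad, miny - pad), (maxx + pad, maxy + pad), size=(n_par, 2))


def _thomas_offspring(
    parents: np.ndarray,
    mean_offspring: float,
    sigma: float,
    roi: Polygon,
    rng: np.random.Generator,
) -> np.ndarray:
    if len(parents) == 0:
        return np.zeros((0, 2))
    counts = rng.poisson(mean_offspring, size=len(parents))
    centers = np.repeat(parents, counts, axis=0)
    pts = centers + rng.normal(scale=sigma, size=centers.shape)
    if len(pts) == 0:
        return np.zeros((0, 2))
    keep = shapely.contains_xy(roi, pts[:, 0], pts[:, 1])
    return pts[keep]


def simulate_sample(
    config: SyntheticCohortConfig, sample_seed: int, sample_id: str = "S1"
) -> tuple[CellTable, RegionSet]:
    """Simulate one sample: ROI polygon plus phenotype point patterns.

    Point counts per phenotype are Poisson with mean intensity × area; all
    points are clipped to the ROI.  The same seed always reproduces the
    same table.
    """
    rng = np.random.default_rng(sample_seed)
    roi = _make_roi(config, rng)
    if roi.area == 0:
        raise ValueError("zero-area ROI")
    area_mm2 = roi.area / UM2_PER_MM2

    frames: list[pd.DataFrame] = []
    shared_parents: np.ndarray | None = None

    order = sorted(config.intensities)
    # generate the co-clustering partner first so CD8 can reuse its parents
    if config.co_cluster_partner in order:
        order.remove(config.co_cluster_partner)
        order.insert(0, config.co_cluster_partner)

    for ph in order:
        lam = config.intensities[ph]
        if lam <= 0:
            continue
        pattern = config.pattern_for(ph)
        if pattern.kind == "csr":
            n = rng.poisson(lam * area_mm2)
            pts = _points_in_polygon(roi, n, rng)
        else:
            parents = _thomas_parents(roi, pattern, rng)
            if ph == Phenotype.CD8.value and config.co_cluster_fraction > 0:
                if shared_parents is None:
                    raise ValueError(
                        "co-clustering requires a Thomas pattern for the partner phenotype"
                    )
                n_share = int(round(config.co_cluster_fraction * len(parents)))
                take = rng.choice(
                    len(shared_parents),
                    size=n_share,
                    replace=n_share > len(shared_parents),
                )
                parents = np.concatenate(
                    [shared_parents[take], parents[: len(parents) - n_share]]
                )
            mean_offspring = lam / pattern.parents_per_mm2
            pts = _thomas_offspring(parents, mean_offspring, pattern.sigma_um, roi, rng)
            if ph == config.co_cluster_partner:
                shared_parents = parents
        if ph == Phenotype.CD8.value:
            ki67 = rng.random(len(pts)) < config.cd8_ki67_fraction
            labels = np.where(
                ki67, Phenotype.CD8_KI67POS.value, Phenotype.CD8_KI67NEG.value
            )
        else:
            labels = np.full(len(pts), ph)
        frames.append(pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1], "phenotype": labels}))

    data = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["x_um", "y_um", "phenotype"])
    )
    cells = CellTable(sample_id=sample_id, data=data)
    regions = RegionSet(sample_id=sample_id, polygons=[(roi, RegionClass.TUMOR.value)])
    return cells, regions


def simulate_expression(
    gad_norm: pd.Series, config: SyntheticCohortConfig, seed: int
) -> ExpressionMatrix:
    """Expression matrix with planted Spearman correlations to GAD_norm.

    Planted gene g is coupled to the GAD_norm ranks through a Gaussian
    copula with latent Pearson correlation 2·sin(π·ρ_g/6), which yields
    Spearman correlation ρ_g in expectation; null genes are independent.
    Values are shifted to per-gene baselines drawn on a log2 RPKM-like
    scale.
    """
    if gad_norm.isna().any():
        raise ValueError("all samples must have a defined GAD_norm for planting")
    n = len(gad_norm)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    missing = set(config.planted_rho) - set(genes)
    if missing:
        raise ValueError(f"planted genes outside the gene universe: {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    from scipy import stats as _st

    ranks = _st.rankdata(gad_norm.to_numpy(dtype=float))
    z_param = _st.norm.ppf((ranks - 0.5) / n)

    values = np.empty((config.n_genes, n))
    baselines = rng.uniform(1.0, 8.0, size=config.n_genes)
    for i, g in enumerate(genes):
        eps = rng.normal(size=n)
        rho_s = config.planted_rho.get(g, 0.0)
        rho_l = 2.0 * math.sin(math.pi * rho_s / 6.0)
        z = rho_l * z_param + math.sqrt(1.0 - rho_l**2) * eps
        values[i] = baselines[i] + z
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=gad_norm.index)
    )


def simulate_cohort(config: SyntheticCohortConfig) -> CohortBundle:
    """Simulate a full cohort and record its ground truth in a manifest.

    Per-sample seeds are derived deterministically from ``config.rng_seed``;
    the manifest records patterns, planted correlations, the shared-parent
    fraction, seeds and the expected GAD_norm regime, and round-trips
    through JSON unchanged.
    """
    master = np.random.default_rng(config.rng_seed)
    seeds = master.integers(0, 2**31 - 1, size=config.n_samples + 1)

    cells: dict[str, CellTable] = {}
    regions: dict[str, RegionSet] = {}
    for i in range(config.n_samples):
        sid = f"S{i + 1:03d}"
        cells[sid], regions[sid] = simulate_sample(config, int(seeds[i]), sample_id=sid)

    expression = None
    gad_norm = None
    if config.n_genes > 0:
        gad_norm = pd.Series(
            {
                sid: sample_distance_result(cells[sid], regions[sid], config.gad_source).gad_norm
                for sid in sorted(cells)
            }
        )
        if gad_norm.notna().all():
            expression = simulate_expression(gad_norm, config, int(seeds[-1]))

    pattern_kind = config.pattern_for(config.gad_source).kind
    if pattern_kind == "csr":
        regime = "csr"
    elif config.co_cluster_fraction > 0:
        regime = "co_clustered"
    else:
        regime = "myeloid_clustered"

    manifest = {
        "n_samples": config.n_samples,
        "roi_shape": config.roi_shape,
        "roi_area_mm2": config.roi_area_mm2,
        "intensities": dict(config.intensities),
        "patterns": {ph: asdict(p) for ph, p in config.patterns.items()},
        "co_cluster_fraction": config.co_cluster_fraction,
        "co_cluster_partner": config.co_cluster_partner,
        "planted_rho": dict(config.planted_rho),
        "gad_source": config.gad_source,
        "rng_seed": int(config.rng_seed),
        "sample_seeds": [int(s) for s in seeds[:-1]],
        "expression_seed": int(seeds[-1]),
        "expected_gad_norm_regime": regime,
        "gad_norm": None if gad_norm is None else {k: float(v) for k, v in gad_norm.items()},
    }
    return CohortBundle(cells=cells, regions=regions, expression=expression, manifest=manifest)
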