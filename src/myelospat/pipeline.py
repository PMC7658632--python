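"""End-to-end orchestration: cohort → spatial metrics → signatures → reports.

Stages are pure functions over in-memory objects; :func:`run_pipeline` wires
them together, writes tidy CSV outputs and a JSON run manifest, and is
deterministic: identical config + seed reproduce byte-identical result
files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import build_hex_grid
from .io_model import (
    Cohort,
    MYELOID_TYPES,
    Phenotype,
    RegionClass,
    RunConfig,
    read_inputs,
    write_cells,
    write_expression,
    write_regions,
)
from .signatures import (
    GeneSignature,
    correlate_genes_with_parameter,
    derive_distance_signature,
    permutation_test,
    score_signed_signature,
)
from .spatial_metrics import (
    CohortThresholds,
    cohort_thresholds,
    compute_density,
    sample_distance_result,
    sample_overlap_result,
    stratify_sample,
)
from .synthetic import SyntheticCohortConfig, simulate_cohort

#: phenotypes whose tumor densities enter the cohort density table
DENSITY_PHENOTYPES = [
    Phenotype.CD8.value,
    Phenotype.CD8_KI67POS.value,
    Phenotype.CD8_KI67NEG.value,
    Phenotype.CD11B_CD14.value,
    Phenotype.CD11B_CD15.value,
    Phenotype.ARG1.value,
    Phenotype.FOXP3.value,
]


@dataclass
class SpatialResults:
    densities: pd.DataFrame  # samples × phenotypes, cells/mm² in the tumor ROI
    distances: pd.DataFrame  # tidy: sample_id, myeloid_type, gad, n, area_mm2, gad_norm
    overlap: pd.DataFrame  # tidy: sample_id, myeloid_type, mto, category, levels
    thresholds: CohortThresholds
    warnings: list[str] = field(default_factory=list)


def compute_spatial(cohort: Cohort, config: RunConfig | None = None) -> SpatialResults:
    """Densities, GAD/GAD_norm, MTO and 4-category strata for a cohort.

    Samples with no myeloid or CD8 cells in the tumor ROI yield missing
    GAD/MTO; they are excluded from cohort medians and listed in the
    warnings (an audit trail rather than silent dropping).
    """
    config = config or RunConfig()
    warnings: list[str] = []
    sample_ids = sorted(set(cohort.cells) & set(cohort.regions))
    for sid in sorted(set(cohort.cells) - set(cohort.regions)):
        warnings.append(f"sample {sid!r} skipped: no region annotations")

    dens_rows, dist_rows = {}, []
    grids = {}
    grid_cache: dict[bytes, object] = {}
    for sid in sample_ids:
        cells, regions = cohort.cells[sid], cohort.regions[sid]
        dens_rows[sid] = {
            ph: compute_density(cells, regions, RegionClass.TUMOR.value, ph)
            for ph in DENSITY_PHENOTYPES
        }
        roi = regions.class_union(RegionClass.TUMOR.value)
        key = roi.wkb
        if key not in grid_cache:
            grid_cache[key] = build_hex_grid(
                roi, diagonal=config.hex_diagonal, min_coverage=config.min_tile_coverage
            )
        grids[sid] = grid_cache[key]
        for mt in MYELOID_TYPES:
            res = sample_distance_result(cells, regions, mt)
            dist_rows.append(
                {
                    "sample_id": sid,
                    "myeloid_type": mt,
                    "gad": res.gad,
                    "n": res.n,
                    "area_mm2": res.area_mm2,
                    "gad_norm": res.gad_norm,
                }
            )
            if not res.defined:
                warnings.append(
                    f"sample {sid!r}: GAD undefined for {mt} (empty cell population)"
                )

    densities = pd.DataFrame.from_dict(dens_rows, orient="index").rename_axis("sample_id")
    distances = pd.DataFrame(dist_rows)

    thresholds = cohort_thresholds(densities)

    mto_rows = []
    for sid in sample_ids:
        for mt in MYELOID_TYPES:
            res = sample_overlap_result(
                cohort.cells[sid], cohort.regions[sid], grids[sid], thresholds, mt
            )
            mto_rows.append({"sample_id": sid, "myeloid_type": mt, "mto": res.mto})
            if not res.defined:
                warnings.append(f"sample {sid!r}: MTO undefined for {mt} (no CD8-hot tile)")
    overlap = pd.DataFrame(mto_rows)

    mto_wide = overlap.pivot(index="sample_id", columns="myeloid_type", values="mto")
    thresholds = cohort_thresholds(densities, mto_wide)

    strata = []
    for row in overlap.itertuples():
        assignment = stratify_sample(
            row.sample_id,
            row.myeloid_type,
            densities.loc[row.sample_id, Phenotype.CD8.value],
            row.mto,
            thresholds,
        )
        strata.append(
            {"category": np.nan, "cd8_level": "", "mto_level": ""}
            if assignment is None
            else {
                "category": assignment.category,
                "cd8_level": assignment.cd8_level,
                "mto_level": assignment.mto_level,
            }
        )
    overlap = pd.concat([overlap, pd.DataFrame(strata)], axis=1)
    return SpatialResults(
        densities=densities,
        distances=distances,
        overlap=overlap,
        thresholds=thresholds,
        warnings=warnings,
    )


@dataclass
class SignatureResults:
    gene_correlations: dict[str, pd.Series]  # myeloid type → per-gene Spearman R
    signatures: dict[str, GeneSignature]
    scores: pd.DataFrame  # samples × signatures, signed centered scores
    permutations: dict[str, dict] = field(default_factory=dict)


def compute_signatures(
    cohort: Cohort,
    spatial: SpatialResults,
    config: RunConfig | None = None,
    sgoi_genes: list[str] | None = None,
) -> SignatureResults:
    """Derive and score GAD-correlated gene signatures.

    For each myeloid type, every gene is Spearman-correlated with the
    per-sample GAD_norm, thresholded at the configured |R| cutoff into a
    signed signature, and the signature is scored across the cohort.  Any
    requested genes of interest are tested against each signature with the
    random-signature permutation test.
    """
    if cohort.expression is None:
        raise ValueError("cohort has no expression matrix")
    config = config or RunConfig()
    cutoffs = {
        Phenotype.CD11B_CD14.value: config.signature_cutoff_cd14,
        Phenotype.CD11B_CD15.value: config.signature_cutoff_cd15,
    }
    short = {Phenotype.CD11B_CD14.value: "GAD_CD14", Phenotype.CD11B_CD15.value: "GAD_CD15"}

    correlations, sigs, score_cols, perms = {}, {}, {}, {}
    for mt in MYELOID_TYPES:
        sub = spatial.distances.query("myeloid_type == @mt").set_index("sample_id")
        param = sub["gad_norm"]
        gene_r = correlate_genes_with_parameter(cohort.expression, param)
        correlations[mt] = gene_r
        sig = derive_distance_signature(
            gene_r, cutoffs[mt], name=f"{short[mt]}_signature", source_parameter=short[mt]
        )
        sigs[mt] = sig
        if sig.size:
            score_cols[sig.name] = score_signed_signature(cohort.expression, sig)
            for gene in sgoi_genes or []:
                res = permutation_test(
                    cohort.expression,
                    sig,
                    gene,
                    n_permutations=config.n_permutations,
                    seed=config.rng_seed,
                )
                perms[f"{sig.name}:{gene}"] = {
                    "observed_correlation": res.observed_correlation,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                    "rng_seed": res.rng_seed,
                }
    scores = pd.DataFrame(score_cols)
    scores.index.name = "sample_id"
    return SignatureResults(
        gene_correlations=correlations, signatures=sigs, scores=scores, permutations=perms
    )


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, index: bool) -> None:
    df.to_csv(path, index=index, float_format="%.10g")


def run_pipeline(config: dict, outdir) -> Path:
    """Run the full pipeline from a config mapping and write results.

    Config keys: ``simulate`` (SyntheticCohortConfig fields) or ``inputs``
    (``cells``/``regions``/``expression`` paths), ``analysis`` (RunConfig
    fields) and optional ``sgoi_genes``.  Produces densities.csv,
    distances.csv, overlap.csv, a signatures/ directory and manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_config = RunConfig.from_dict(config.get("analysis", {}))

    outputs: list[str] = []
    warnings: list[str] = []
    if "simulate" in config:
        sim_cfg = SyntheticCohortConfig(**config["simulate"])
        bundle = simulate_cohort(sim_cfg)
        cohort = bundle.as_cohort()
        write_cells(cohort.cells, outdir / "cells.csv")
        write_regions(cohort.regions, outdir / "regions.geojson")
        outputs += ["cells.csv", "regions.geojson"]
        if cohort.expression is not None:
            write_expression(cohort.expression, outdir / "expression.tsv")
            outputs.append("expression.tsv")
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(bundle.manifest, fh, indent=1, sort_keys=True)
        outputs.append("ground_truth.json")
    elif "inputs" in config:
        paths = config["inputs"]
        cohort = read_inputs(
            paths["cells"], paths["regions"], paths.get("expression")
        )
        warnings += cohort.warnings
    else:
        raise ValueError("config needs either a 'simulate' or an 'inputs' section")

    spatial = compute_spatial(cohort, run_config)
    warnings += spatial.warnings
    _write_csv(spatial.densities, outdir / "densities.csv", index=True)
    _write_csv(spatial.distances, outdir / "distances.csv", index=False)
    _write_csv(spatial.overlap, outdir / "overlap.csv", index=False)
    outputs += ["densities.csv", "distances.csv", "overlap.csv"]
    with open(outdir / "thresholds.json", "w") as fh:
        json.dump(
            {
                "density_medians": spatial.thresholds.density_medians,
                "cd8_density_median": spatial.thresholds.cd8_density_median,
                "mto_medians": spatial.thresholds.mto_medians,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    outputs.append("thresholds.json")

    if cohort.expression is not None:
        sig_dir = outdir / "signatures"
        sig_dir.mkdir(exist_ok=True)
        sig_res = compute_signatures(
            cohort, spatial, run_config, sgoi_genes=config.get("sgoi_genes")
        )
        for mt, sig in sig_res.signatures.items():
            sig.to_tsv(sig_dir / f"{sig.name}.tsv")
            outputs.append(f"signatures/{sig.name}.tsv")
            corr = sig_res.gene_correlations[mt].rename("spearman_r")
            _write_csv(corr.to_frame(), sig_dir / f"{sig.name}_gene_correlations.csv", index=True)
            outputs.append(f"signatures/{sig.name}_gene_correlations.csv")
        if not sig_res.scores.empty:
            _write_csv(sig_res.scores, sig_dir / "scores.csv", index=True)
            outputs.append("signatures/scores.csv")
        if sig_res.permutations:
            with open(sig_dir / "permutations.json", "w") as fh:
                json.dump(sig_res.permutations, fh, indent=1, sort_keys=True)
            outputs.append("signatures/permutations.json")

    manifest = {
        "software": {"name": "myelospat", "version": __version__},
        "config": config,
        "config_hash": _config_hash(config),
        "outputs": sorted(outputs),
        "warnings": warnings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir
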