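# Methods

## Coordinate frame, units and inputs

All geometry is planar, in micrometres, y increasing downward (image
convention). Areas are reported in mm² and densities in cells/mm². All
spatial statistics used here are invariant to translation, rotation and the
choice of origin, so any consistent planar frame from a scanner export is
acceptable. Cell phenotypes come from a closed vocabulary (CD8 with or
without Ki67 split, CD11b+CD14+, CD11b+CD15+, ARG1+, FOXP3+, Ki67+ tumor
cells); the total CD8 compartment is the union of the aggregate and
Ki67-split labels, and a sample may not mix the two representations.
Excluded regions (necrosis, artefacts) are subtracted from every region
class before any area or density computation.

## Nearest-neighbor distance and its normalization

For one sample and one myeloid type, every CD8+ cell in the tumor ROI is
assigned to its nearest myeloid cell (k-d tree, Euclidean metric); the mean
pair distance is the global average distance, GAD. Under complete spatial
randomness the expected distance from an arbitrary point to the nearest
point of a homogeneous Poisson process of intensity λ = n/A is 1/(2√λ) =
0.5·√(A/n) (Clark–Evans), so

    GAD_norm = GAD / (0.5·√(A/n)),   A in µm².

No edge correction is applied; on realistic ROI sizes this leaves a small
upward bias (the CSR calibration experiment measures a mean GAD_norm of
about 1.02–1.03 rather than 1.00 on a 5 mm² ROI with ~500 myeloid cells).
Samples with zero CD8 or zero myeloid cells in the ROI have undefined
GAD/GAD_norm; they are excluded from cohort medians and contrasts and
surfaced as warnings rather than silently dropped.

## Hexagonal tessellation and the overlap score

The tumor ROI is covered with pointy-top regular hexagons. The configured
"diagonal" (default 250 µm) is read as the long, vertex-to-vertex diagonal,
i.e. circumradius R = 125 µm and tile area (3√3/2)·R² ≈ 0.0406 mm²; the
long diagonal is the conventional meaning of a hexagon's diagonal length.
The grid is anchored at the lower-left corner of the ROI bounding box so
runs are reproducible. Edge handling is explicit: a tile is retained only
if its intersection with the ROI covers at least 50% of the full hexagon
area (`RunConfig.min_tile_coverage`), and tile densities are computed over
the clipped intersection area, which avoids density inflation in sliver
tiles. Cells falling in dropped tiles are counted nowhere and reported, so
tile counts plus dropped counts always conserve the input.

Point-to-tile assignment uses the fact that the hexagons are the Voronoi
cells of their centers: each point is assigned by exact nearest-center
search over the rounded axial cell and its six neighbors. A point exactly
equidistant between centers goes to the retained tile with the lower index
(and retained tiles win ties against dropped ones), a measure-zero
tie-break that makes counts deterministic.

Tile *i* is hot for cell type *j* iff its density strictly exceeds D_j, the
cohort median of *sample-level* tumor densities of type j (not a per-tile
median). MTO is the number of tiles hot for both CD8 and the myeloid type,
divided by the number of CD8-hot tiles; it is undefined when a sample has
no CD8-hot tile.

## Stratification

Samples are assigned by (CD8 tumor density, MTO) relative to the cohort
medians: low/low → category 1, low/high → 2, high/high → 3, high/low → 4.
"High" means strictly above the median; values at the median map to "low"
so that category counts are reproducible. With distinct values this splits
each axis ⌊n/2⌋ / ⌈n/2⌉. Categories are computed per myeloid type
(CD11b_CD14 and CD11b_CD15 stratifications side by side), since the two
need not agree; downstream differential-expression tools consume these
labels externally.

## Invasive margin

The invasive-margin band is the set difference of the tumor polygon dilated
and eroded by the half-width (default 250 µm, i.e. a 500 µm band straddling
the boundary). Where normal tissue is annotated the band is clipped to
annotated tissue; excluded regions are always subtracted. Band area is
validated against a closed-form annulus and an independent 2 µm raster
oracle.

## Gene-set scoring and distance signatures

Within each sample, genes are midranked and a gene set is scored by the
rank-biserial correlation r_rb = 2U/(n₁n₂) − 1 of set genes against all
other genes of the matrix (the full matrix is the background; a filtered
background can be emulated by subsetting the matrix before scoring). Scores
are multiplied by 10 and median-centered per signature across samples.
Because the score is purely rank-based it is invariant to any monotone
per-sample transform of expression.

Distance signatures are derived by Spearman-correlating every gene with the
per-sample GAD_norm (pairwise deletion of samples with undefined values;
at least 4 pairs required) and keeping genes with R strictly above the
cutoff (positive set) or strictly below its negative (negative set);
defaults are 0.4 for GAD_CD14 and 0.3 for GAD_CD15. A signed signature is
scored as positive-set minus negative-set centered scores — the combination
rule is this package's choice, made to preserve the sign semantics of the
derivation; both single-set scores remain available via `score_gene_set`.

The permutation test draws random signatures matching the derived
positive/negative sizes exactly, without replacement from the full gene
universe, with a seeded generator. The p-value is the fraction of random
signatures whose |Spearman r| with the gene/signature of interest strictly
exceeds the observed |r|; there is no pseudo-count, so p can be exactly 0.
Internally the observed and permuted statistics use the raw signed
rank-biserial difference, which is monotone-equivalent to the ×10
median-centered score (Spearman only sees ranks) and avoids float noise on
exact ties.

## Synthetic cohorts

The generator emulates what the pipeline consumes, with recorded ground
truth; it makes no attempt to model stain intensity, segmentation error or
real tumor architecture, so passing tests demonstrate correctness of the
statistics, not biological fidelity of any simulation.

* ROI: a square of configurable area (default 5 mm²) or a star-convex blob.
* Point patterns: per phenotype, CSR (Poisson counts, uniform placement) or
  a Thomas cluster process — Poisson parents (default 5/mm²) on a window
  extended by 4σ so clusters straddle the edge, Poisson offspring counts,
  isotropic Gaussian displacement (default σ = 30 µm). The per-parent
  offspring mean is derived from the phenotype's intensity so pattern
  choice never changes expected abundance. Co-localization is planted by
  letting a fraction of CD8 parents be drawn from the myeloid parent set.
* Default intensities are realistic tumor-ROI medians for treatment-naive
  colorectal cohorts: 76.64 (CD8), 35.32 (CD11b_CD14), 122.12 (CD11b_CD15),
  129.89 (FOXP3) cells/mm², with ARG1 at 100 and Ki67+ tumor cells at 500
  cells/mm² and a default cohort size of 74 samples.
* Expression: planted genes are coupled to the ranks of the realized
  GAD_norm through a Gaussian copula with latent correlation
  2·sin(π·ρ/6), which yields the target Spearman ρ in expectation
  regardless of marginals; null genes are independent normals. Per-gene
  baselines are drawn on a log2 RPKM-like scale (uniform 1–8, unit sd).

Per-sample seeds derive deterministically from the cohort seed; the
manifest records all ground truth and round-trips through JSON.

## Calibration experiments and problem sizes

`myelospat.validation` fixes the experiment conditions: single samples with
~500 myeloid and ~200 CD8 cells in a 5 mm² ROI for GAD_norm calibration
(50 seeds; CSR mean in [0.98, 1.10], clustered mean > 1.15, co-clustered
mean < 0.9); cohorts of 6 samples × 20 seeds per co-clustering fraction for
MTO monotonicity; 80-sample, 200-gene matrices with 20 genes planted at
|ρ| = 0.6 for signature recovery at the |R| > 0.4 cutoff; and 200 trials of
500 permutations for the null-uniformity check of permutation p-values.
These sizes give stable means at seconds-to-a-minute runtimes on one CPU
while leaving each effect far larger than its Monte-Carlo error.

## Known limitations

* No edge correction in GAD_norm; strongly non-convex or very small ROIs
  increase the upward CSR bias.
* Hot-tile thresholds assume the cohort is large enough for stable medians;
  with < ~6 samples the stratification is fragile by construction.
* The generator's clustering is stationary and isotropic; real tumors have
  anisotropic stroma-driven structure the simulation does not reproduce.
* Registration of serial sections is assumed done upstream: all phenotypes
  of a sample must live in one coordinate frame.
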