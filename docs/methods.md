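# Methods

This note records the models, conventions and design decisions behind
`sstbench`, in the spirit of the methods documentation of simulation and
statistics packages: what each procedure assumes, which knobs matter, and
what the synthetic validation does and does not demonstrate.

## Data model and conventions

Spot coordinates are continuous micrometres with an arbitrary origin.  All
grid cells, windows and profile bins are **half-open** intervals
`[a, b)`, and membership of a spot is always decided by its centre point;
this guarantees that partitions of the plane never count a spot twice.
Points lying exactly on a region-of-interest boundary count as inside
(deterministic and documented, since the alternative is arbitrary).
Matrix Market files use 1-based indices on disk and 0-based internally,
with barcodes (spots) in rows.

## Quality filtering and normalisation

Low-quality spots are removed when their total count falls below 30 % of
the **first quartile** of per-spot totals.  The quartile is the 25th
percentile with type-7 linear interpolation (the numpy/R default).  We
read "first quantile" as the first quartile rather than the 1st
percentile: the 25th percentile is the only reading under which a 30 %
factor defines a meaningful low-count cut, and it matches common QC
practice.  At least four spots are required, otherwise the quartile is
ill-defined and the operation raises.

Normalisation scales each spot to the **median** per-spot total (each
normalised row sums to the median).  It requires strictly positive totals
and is therefore always run after the QC filter (pipeline code drops
zero-total spots that appear after heavy downsampling before
renormalising).

## Synthetic data generator

The generator emulates the statistical structure of multi-platform sST
data, not any particular chemistry:

1. `n_cells` cells are placed uniformly over the layout bounding box and
   labelled by region (concentric rings or parallel layers).
2. Each cell emits, per gene, Poisson(rate) molecules at the region's
   programmed rate (expected molecules per cell).
3. Ambient genes emit Poisson(rate × contamination_fraction × n_cells)
   molecules uniformly over the capture area — a tissue-wide background
   like blood hemoglobin, independent of local cell type.
   `contamination_fraction = 0` switches contamination off; the ambient
   load scales with tissue size like the cellular signal does.
4. Every molecule is displaced by an isotropic Gaussian with s.d.
   `sigma_diff_um` (lateral diffusion).  A Gaussian displacement is a
   modelling choice: it is the simplest isotropic kernel with a single
   scale parameter, and the diffusion statistics below only assume that
   larger σ spreads molecules further.
5. The molecule is captured by the nearest spot centre iff it lies within
   `spot_diameter_um / 2`; otherwise it is lost.  This creates realistic
   dead space between spots on coarse arrays and makes capture efficiency
   an emergent function of geometry.
6. Each captured molecule receives `1 + Poisson(mean − 1)` sequencing
   reads — the simplest duplication model that guarantees ≥ 1 read per
   observed molecule and produces non-trivial saturation curves.

All draws come from a single `numpy` generator seeded once, in exactly the
order above, so a seed fully determines the dataset.  What the generator
does **not** model: PCR/sequence-dependent amplification bias, barcode
errors, segmentation, cell-size variation, anisotropic or tissue-dependent
diffusion.  Tests passing on this generator therefore validate the
*statistics* (that LWHM tracks the diffusion scale, that the downsampler is
unbiased, that the entropy metrics are correct), not any claim about a
specific real platform.

## Read downsampling and saturation

Depth matching samples reads **without replacement** from the pooled reads
of all molecules — the exact analogue of drawing sequencing read IDs — via
the multivariate hypergeometric distribution over per-molecule read
counts.  A binomial-thinning mode (independent per-read keep probability)
is available behind a flag for comparison; it does not hit the target
depth exactly.  Proportions are converted to read counts by round-half-up
so runs are reproducible across platforms.  The closed-form expectation
`expected_umis` is an independent oracle used by the tests; it is exact,
nondecreasing and concave in the target depth.

## Diffusion statistics

A strip ("modality") is an anchored, oriented rectangle; spot centres
within half the strip width of the axis are binned half-open along it.
The profile peak is the argmax, leftmost bin on ties.  **LWHM** is
`peak_position − crossing_position`, where the crossing is found by
scanning left from the peak for the first bin strictly below half the peak
value and interpolating linearly between that bin centre and its right
neighbour.  Profiles that never drop below half to the left (flat or
monotone-left) have no defined LWHM and are excluded from summaries rather
than raising — mixing them in as zeros or infinities would bias medians.
LWHM is invariant to scaling the profile, hence unchanged by area-under-
curve normalisation (used only for display).

Peak alignment before averaging shifts profiles so their argmax bins
coincide and truncates to the common overlap; profiles with totals below a
configurable minimum (default 10 counts) are dropped first, since an
argmax on noise is meaningless.  The overlap-truncation rule is a design
choice for unequal strip lengths.

The DBSCAN dispersion statistic clusters expressing spots
(`count > 0`) with `eps` defaulting to twice the spot pitch and
`min_samples = 3` (both configurable — no canonical values exist), then
reports per-cluster mean count and the sample variance of member distances
to the centroid.  A pairwise-distance variant is available behind a flag;
the centroid reading is the default because it has an unambiguous "spread
around a source" interpretation.

### Parameter recovery scenario

`sstbench.scenarios.ring_band_scenario` places a 10 μm-wide marker band at
radius 100–110 μm on a dense 1 μm-pitch array; `measure_boundary_lwhm`
profiles it along eight 30 μm-wide radial strips with 10 μm bins and takes
the median LWHM.  The bin width matches the band so that at σ = 0 the band
occupies a single bin and the left crossing is sharp (LWHM ≈ 5 μm, half a
bin); narrow strips keep ring curvature from smearing the radial
coordinate.  With 10 000 cells the median LWHM separates σ = 0, 5 and
20 μm cleanly in every seeded replicate.

## Clustering entropies

ECA and ECP are computed from the contingency table over the spots shared
by both labelings (spots present in only one labeling are dropped and
logged).  ECA is the mean, over predicted clusters, of the natural-log
entropy of reference labels within the cluster; ECP mirrors it over
reference classes — equivalently `ecp(pred, ref) == eca(ref, pred)`.
Natural logarithms are used so values are comparable to `ln k` bounds.
This conditional-entropy formulation is the standard reading of
"accuracy/purity entropy"; the heatmap display transform is
`log10(n + 1)`.

## Marker detection

The per-gene test is the two-sided Wilcoxon rank-sum on median-normalised
expression: exact null when the combined group size is ≤ 25 and the pooled
values are tie-free, otherwise the normal approximation with tie and
continuity corrections (a constant gene short-circuits to p = 1).  The
log fold change is `ln((mean₁ + ε) / (mean₂ + ε))` with ε = 10⁻⁹ on
normalised counts — a deliberate simplification of expm1-mean formulas
used by some toolkits, chosen for transparency.  Benjamini–Hochberg runs
across **all** tested genes with no pre-filtering.  The marker filter
applies three strict inequalities: detection fraction in the up-regulated
group > 0.05 (one-group reading), ln fold change > 0.25, adjusted
P < 0.01.  On null data the test is calibrated (type-I fraction at
p < 0.05 within Monte-Carlo error of 0.05 for 500 genes at 50 + 50 spots).

The marker-depth curve re-runs the entire pipeline (downsample →
re-quantify → QC filter → renormalise → test → filter) per proportion;
groups are intersected with surviving spots, and fewer than two spots per
group yields zero markers by definition.

## Gene-capture bias

The pairwise rule flags genes at or above the `high_q` quantile of one
platform's totals and at or below the `low_q` quantile of another's
(type-7 quantiles; ≥/≤ at the quantile values, which matters for small
panels).  Both a strict 99th-percentile and a relaxed 90th-percentile
preset are shipped, paired with a 10th-percentile lower cut; exact
recovery of planted genes with zero false positives is only guaranteed for
the strict preset — at 90th/10th, independent background totals are
expected to produce ~n × 0.1 × 0.1 coincidental flags.  The multi-platform
rule takes genes strictly above the 90th percentile in **every** non-focal
platform and splits them at an absolute focal total of 30; that absolute
cut is depth-dependent, so it is exposed as a parameter.  Attribute
association uses one-way ANOVA (two groups, so F is the squared t) on GC
fraction or gene length.

## Problem sizes and tolerances

The validation suite runs entirely on synthetic data at sizes chosen to
make every stochastic assertion sharp but quick: 1 000 replicate
downsamples of a 100-molecule table against the closed form (3 s.e.
band), 500-gene null calibration (3 s.e. of a 5 % binomial), ten seeded
triplets of the diffusion-recovery experiment at 10 000 cells, and demo
pipelines at a few hundred cells per platform.  Exact assertions
(entropies, triangle LWHM, quantile fixtures, rank-sum enumeration) use
tolerances of 10⁻¹² or tighter.  `scripts/acceptance.py` re-runs the same
computations from scratch with sizes fixed by the script and all
randomness derived from `--seed`.

## Known limitations

- Cluster labels are inputs: no clustering algorithm is part of the
  evaluated surface (the pipeline's k-means is demo plumbing only).
- LWHM is a 1-D surrogate; no 2-D kernel deconvolution or physical
  diffusion coefficient is estimated.
- The generator's uniform cell placement and single global diffusion σ are
  idealisations; region-dependent density or diffusion would require
  extending `simulate_dataset`.
- `low_cut = 30` in the bias rule and the `min_total = 10` profile filter
  are absolute-count conventions; both depend on sequencing depth and are
  parameters, not recommendations.
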