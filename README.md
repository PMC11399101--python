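# sstbench

Benchmarking computations for **sequencing-based spatial transcriptomics
(sST)** — the family of methods that capture transcripts on spatially
barcoded spot arrays (bead arrays, DNA nanoball grids, barcoded slides) and
read them out by sequencing.  Platforms differ enormously in spot pitch,
capture efficiency, sequencing depth and lateral spread of transcripts, so
comparing them fairly requires a specific set of statistics.  `sstbench`
implements that set as a tested Python library, together with a synthetic
data generator with known ground truth so every statistic can be validated
end to end.

Intended users: method developers and analysts comparing sST platforms, and
anyone who needs the individual building blocks (read-level downsampling,
saturation curves, profile half-width measures, clustering entropies).

## What it computes

- **Depth matching and saturation** (`sstbench.depth`).  Reads are sampled
  uniformly without replacement from the pooled reads of all molecules
  (multivariate hypergeometric); a molecule (UMI) survives iff at least one
  of its reads is drawn.  The saturation curve reports distinct UMIs versus
  read depth, and the exact expectation is available in closed form:
  E[UMIs] = Σ_m [1 − C(R−r_m, T) / C(R, T)] for molecules with r_m of R
  reads when T reads are kept.
- **Capture sensitivity** (`sstbench.sensitivity`).  Total UMIs in a region
  of interest and marker-gene UMI sums in fixed windows (default
  50 × 50 μm), with mean/s.d. across windows and a cross-platform ranking
  at matched depth.
- **Lateral diffusion** (`sstbench.diffusion`).  1-D intensity profiles of
  a boundary marker along rectangular strips; the **left-width at
  half-maximum (LWHM)** — the distance from the profile peak leftward to
  the linearly interpolated half-maximum crossing — quantifies how far
  transcripts spread past a sharp histological boundary.  Only the left
  width is used, because genuine expression on the right of the boundary
  would otherwise masquerade as diffusion.  A DBSCAN-based dispersion
  statistic (variance of member distances to the cluster centroid) covers
  sparsely expressed markers.
- **Clustering agreement** (`sstbench.cluster_eval`).  From the contingency
  table of two labelings, the **entropy of cluster accuracy**
  ECA = −(1/M) Σ_i Σ_j p_ij ln p_ij (p_ij the reference-label mix inside
  predicted cluster i) and the **entropy of cluster purity** ECP, the
  mirror image over reference classes.  Both are 0 exactly at perfect
  agreement.
- **Marker detection** (`sstbench.markers`).  Two-sided Wilcoxon rank-sum
  test per gene on median-normalised counts, Benjamini–Hochberg
  adjustment, and the three-threshold filter (detection in > 5 % of the
  up-regulated group's spots, ln fold change > 0.25, adjusted P < 0.01);
  marker counts versus read depth and upset-style marker-set intersections.
- **Gene-capture bias and contamination** (`sstbench.bias`).  Pairwise
  percentile rule (top tail in one platform, bottom decile in another; 99th
  and 90th presets), multi-platform bias-gene flagging (high everywhere,
  < 30 counts in the focal platform), one-way ANOVA of GC fraction and gene
  length between bias and comparison genes, biotype summaries, and the
  fraction of spots expressing a blood-like gene.
- **Synthetic data** (`sstbench.synthetic`).  Ring or layered tissue
  layouts, region expression programs, Poisson molecule emission, isotropic
  Gaussian lateral diffusion, nearest-spot capture with dead space, shifted-
  Poisson read duplication and uniform ambient contamination — all from one
  seeded generator.

## Worked example

```sh
python examples/04_diffusion_lwhm.py
```

```
generative sigma   0.0 um -> median LWHM   5.16 um
generative sigma   5.0 um -> median LWHM   7.88 um
generative sigma  20.0 um -> median LWHM  26.70 um
```

The same ring-shaped tissue is simulated at three diffusion levels; the
median LWHM of the band marker's radial profile grows with the true
diffusion scale, which is exactly what the statistic is meant to measure
(at σ = 0 the residual ~5 μm reflects the 10 μm bin width, not diffusion).

The other scripts in `examples/` each demonstrate one capability
(simulation, saturation, sensitivity ranking, clustering entropies, marker
detection, bias rules, the full pipeline) and print a short interpretation.

A thin command line mirrors the library:

```sh
benchkit simulate --seed 4 --out sim
benchkit saturate --molecules sim/beadarray/molecules.tsv \
    --proportions 0.2,0.5,1.0 --reps 5 --seed 1 --out curve.csv
benchkit run --seed 7 --out results/   # full config-driven pipeline
```

## Data formats

Count matrices are Matrix Market coordinate bundles
(`matrix.mtx` + `barcodes.tsv` + `features.tsv` + `positions.csv` with
`barcode,x_um,y_um`); molecule tables are TSV
(`spot_id gene_id molecule_id reads`); regions of interest are JSON
polygons; strips and windows are JSON lists; labels and gene totals are
small CSVs.  Everything is plain text.
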