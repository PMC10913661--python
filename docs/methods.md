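# Methods

This note documents the statistical procedures implemented in `methagene`,
the choices made where several reasonable designs exist, and what the
synthetic-data generator does and does not emulate.

## Data model and conventions

Per-cytosine methylation calls are tuples *(chrom, pos, strand, context,
count_m, count_u)* with 1-based positions, as produced by Bismark-family
callers; context is CG, CHG or CHH (H = A, T or C). Genomic features use
0-based half-open intervals internally; every coordinate conversion happens
once, at the parser boundary (GFF3/GTF and the TSV annotation dialect are
1-based inclusive, BED is already half-open). Records with contexts outside
{CG, CHG, CHH} (e.g. CN, CHN) or unknown strand tokens are dropped and
tallied, never silently ignored; duplicate (chrom, pos, strand) records
keep the first occurrence. Zero-coverage cytosine-report rows are always
excluded; the coverage filter `min_coverage` defaults to 0 (keep every
covered site) so that analyses, not parsers, decide about depth.

**Methylation density** at any aggregation level (site, bin cell, window,
region) is the pooled ratio Σ count_m / Σ (count_m + count_u), not a mean
of per-site fractions. The pooled ratio is robust to low-coverage sites,
whose noisy fractions would otherwise dominate an unweighted mean.

bedGraph input carries density but no read counts. Such sites are stored
with fractional *unit counts* (count_m = density, count_u = 1 − density)
so density-based analyses work unchanged, and the sample is flagged
low-confidence; the gbM classifier refuses these samples because binomial
tests require genuine counts.

## Metagene profiles

Each region is mapped to a fixed grid: `flank_bins` bins over an upstream
window of `flank_length` bp, `body_bins` bins over the body, `flank_bins`
bins downstream. A site at 0-based offset *d* inside a window of length
*L* split into *B* bins falls in bin ⌊d·B/L⌋, clamped so the final base
belongs to the last bin; the computation is pure integer arithmetic, so
bin-edge behaviour is exact and platform independent. Bins are laid out in
genomic orientation and the whole vector is reversed for minus-strand
features, which makes minus-strand binning exactly the reversal of
plus-strand binning (a property the tests assert bit-for-bit).

Defaults: `flank_length` 2000 bp, `body_bins` 100, `flank_bins` 50,
`min_gene_length` 0 — typical metagene settings, all configurable. Flanks
are not masked against neighbouring genes, and a site covered by several
(overlapping) features contributes to each of them: features are analysed
independently.

Across regions the per-bin **mean** is the unweighted mean of per-region
bin densities, so every gene contributes equally regardless of its
coverage. Cells without a covered in-context site are missing values,
excluded from the mean and from the confidence-band *n* — zero-filling
them would bias profiles downward in sparse contexts (CHH especially).

The variability band around the mean is a per-bin t interval,
mean ± t₁₋α/2,ₙ₋₁ · sd/√n with n the number of regions contributing to the
bin (default level 0.95). A band on the mean is what an overlay profile
plot needs; a confidence interval for the standard deviation itself was
the other reading of the requirement and is recoverable from the exported
`sd` and `n_regions` columns.

Smoothing uses a Savitzky–Golay filter (default window 21 bins, polynomial
order 3; the window shrinks to the largest valid odd number on short
grids). Missing bins are linearly interpolated before filtering and
re-flagged as missing afterwards — the filter never fabricates a value for
a bin no data supports. Savitzky–Golay reproduces polynomials up to its
order exactly, which the tests exploit as an oracle (a sampled cubic must
pass through unchanged to 1e-9).

## Heatmaps and distributions

Regions are ranked by their overall methylation density — the mean of the
region's defined bin densities. Ties break lexically by region id and
all-missing regions sort last, so the order is total and reproducible.
When more regions exist than display rows, consecutive rank blocks are
averaged (unweighted nanmean per bin) into super-rows.

The same per-region score feeds violin/box distribution summaries
(quartiles by linear interpolation between order statistics, whiskers at
the most extreme values within 1.5·IQR of the quartile fences). A per-site
variant is available; the region-level view is the default because it
matches the heatmap ranking and is insensitive to per-site depth.

Chromosome tracks tile each chromosome from 0 in non-overlapping windows
(default 100 kb): a site at 1-based position p belongs to window
⌊(p−1)/L⌋. Chromosome extents are inferred from the data (maximum site
position) so no sequence dictionary is required. Window sums conserve the
genome-wide totals exactly, a property the tests assert.

## Gene-body-methylation classification

The classifier follows the two-tier binomial construction of Takuno &
Gaut. Tier 1 (sites): with p̂_c the genome-wide pooled methylation
proportion of context c, a site with m methylated reads of n is *called
methylated* when the upper tail P(X ≥ m | n, p̂_c) ≤ `alpha_site`
(default 0.05). Tier 2 (genes): for each gene and context, the number of
called sites among its N covered body sites is tested against the
genome-wide fraction of called sites of that context — the null that a
gene is a random draw of sites. Gene p-values are Benjamini–Hochberg
adjusted across genes within each context (`fdr_level` default 0.05).

Labels partition the genes: **gbM** (CG q ≤ fdr, CHG and CHH q > fdr),
**CHG/CHH-methylated** (TE-like; CHG or CHH q ≤ fdr, regardless of CG),
**unmethylated** (nothing significant), **undetermined** (fewer than
`min_sites_per_context` covered sites in some context, default 10 — below
that the test has no power and a label would be noise).

Binomial tails are computed through the regularised incomplete beta
function (scipy's survival function), which stays accurate where direct
summation of pᵏ terms underflows (a fully methylated 100-site gene has
p ≈ 0.05¹⁰⁰). Tails match exhaustive enumeration to < 1e-12 over the full
n ≤ 50 grid. BH is implemented directly (sorted step-up with monotonicity
enforcement) and is tested elementwise against the statsmodels
implementation as an independent reference.

## Gene modules (hybrid dynamic tree cut)

Binned profiles are clustered hierarchically (euclidean distance, average
linkage by default; correlation distance and Ward linkage available) and
the dendrogram is cut adaptively rather than at one global height:

* **Tree stage.** Descending from the root, a merge at height *h* is split
  into its branches when *h* stands clear of each branch's *core scatter*
  (the mean merge height inside the branch) by at least a gap proportional
  to the dendrogram height. Using the mean rather than the maximum child
  height matters: with three or more clusters one branch contains a
  between-cluster merge near the top, and a max-based criterion would see
  no gap and never split. `deep_split` (0–4, default 2) maps to gap
  fractions 0.40 … 0.06 — lower values cut conservatively into few
  modules, higher values cut aggressively. Branches smaller than
  `min_module_size` (default 20) join the unassigned pool (module 0).
* **Hybrid stage.** Each unassigned object is adopted by the module with
  the smallest average dissimilarity, provided that dissimilarity is
  within 1.5× the module's own mean internal dissimilarity — the combined
  use of tree shape and raw dissimilarities that defines the *hybrid*
  variant. Objects failing the test stay in module 0.

A dendrogram of identical rows (height 0) yields a single module. Modules
are numbered by decreasing size. Rows with more than 50% missing bins are
excluded to module 0; the remainder have missing bins imputed by
row-internal linear interpolation (distances on missing data are
undefined).

Clustering operates on **raw density profiles** by default. Standardising
rows to zero mean/unit variance ("shape only") was considered and
rejected as the default: a flat profile has near-zero internal variance,
so standardisation amplifies its noise into a random direction and
flat-but-high genes — a genuinely common methylation class — can no longer
form a module (planted-recovery ARI drops from 1.0 to 0.0 in our
simulations). `standardize=True` remains available for profiles with
substantial internal variation.

The test surface for this component is planted-archetype recovery
(adjusted Rand index ≥ 0.9 at within-archetype noise sd 0.02–0.05),
permutation invariance of the partition, and the degenerate identical-rows
case — not agreement with any particular reference implementation.

## Comparison across samples and species

Each labelled entry (sample + its own annotation, possibly from a
different species) is binned and profiled independently on a shared
(body_bins, flank_bins) grid; the comparison layer adds no computation, so
each entry's results are identical to a standalone run (asserted by the
tests). No cross-entry normalisation is applied beyond the common grid —
overlays compare raw density profiles, and no test statistic is computed
between profiles; the comparison is descriptive.

## Synthetic methylomes

The generator emulates the downstream outputs of a WGBS pipeline, not the
sequencing itself. Chromosomes carry non-overlapping genes (uniform length
in a configurable range, random strand, randomised intergenic spacing);
cytosine sites are placed uniformly at context-specific densities
(defaults 20/15/30 sites per kb for CG/CHG/CHH, in the range of compact
plant genomes); per-site read depth is negative binomial (mean 20,
dispersion 5, truncated at 1) to mimic the overdispersion of real
coverage; methylated counts are binomial at the site's true rate.
Background rates default to CG 0.05, CHG 0.03, CHH 0.02. Planted structure
comes in two orthogonal forms: gbM genes (body CG sites at a high within-
gene rate, default 0.8) and profile archetypes (Gaussian bump/dip shapes
along the relative body coordinate, applied 5'→3' so minus-strand genes
are shaped correctly). Every supported input format is written from the
same ground truth, and generation is a pure function of the spec including
its seed — identical specs give byte-identical files.

Not emulated: real sequence context (no FASTA; trinucleotides are
representative placeholders), bisulfite-conversion errors, mapping bias,
copy-number variation, correlated methylation along the genome, and
overlapping or spliced gene models. Passing tests therefore demonstrate
correctness of the computations and calibration of the statistics under
the stated sampling model; they do not certify behaviour under artefacts
absent from that model.

## Determinism and numerical notes

All randomness flows through explicit seeds (numpy `default_rng`). TSV
exports use fixed formatting (6 significant digits, `NA` for missing,
`\n` line endings) and round-trip byte-identically; figures are written
without volatile metadata and the HTML report embeds figures base64 with
no timestamps, so rerunning any CLI subcommand on identical inputs
reproduces identical bytes. Empty bins, all-missing regions, zero-length
intervals, zero-variance rows and single-region matrices are handled
explicitly (missing stays missing; degenerate bands have zero width).

## Problem sizes used by the tests and acceptance script

The simulation scales were chosen to make every statistical check sharp at
interactive runtimes: cross-format fidelity on ~16k sites; the brute-force
binning oracle on 120–200 genes; confidence-band calibration on 1,000
replicates of 50 regions × 5 bins (per-bin empirical coverage is then
within ±1.5 points of the nominal 95% up to Monte-Carlo noise); binomial
tails enumerated exhaustively for n ≤ 50; classifier recovery on 1,000
genes with 100 planted gbM genes (~40–60 covered CG sites each), plus
three 150-gene null replicates; module recovery on 200–300 rows of 50
bins. The full test suite runs in about a minute; the acceptance script
in about fifteen seconds.

## Known limitations

* Flank windows may extend beyond chromosome starts or into neighbouring
  genes; no masking is applied.
* The gbM label taxonomy is the cited reference's convention; organisms
  with pervasive CHH methylation may want different label rules (the
  per-context q-values are all exported, so relabelling is cheap).
* The hybrid tree cut is a compact reimplementation of the hybrid
  cutting idea, tuned through `deep_split`; it is validated against
  planted truth, not against any external implementation's exact output.
* bedGraph input supports density analyses only; classification requires
  a count-bearing format.
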