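# Methods

This note documents the models, conventions and parameter choices behind
`cforigin`, and what the synthetic-data experiments do and do not establish
about real data.

## Marker selection model

A CpG is *specific* to a target cell type when its methylation level β is
below `lo` in **every** target sample and above `hi` in **every** other
sample (hypomethylated marker), or the mirror image (hypermethylated).
Defaults are `lo = 0.20`, `hi = 0.80`, applied as **strict** inequalities: a
sample sitting exactly at a cutoff fails. CpGs lacking coverage in any sample
under comparison are excluded from candidacy rather than imputed — an
uncovered site carries no evidence either way. How the original
marker panels handled partially covered candidate sites is not documented;
exclusion is the conservative choice.

Specific CpGs are promoted to assay-grade marker regions by a density rule:
within each maximal run of same-direction specific CpGs on one chromosome,
every contiguous sub-run of ≥ `min_cpgs` (5) CpGs whose genomic footprint
(last CpG position + 2 − first CpG position) fits in `window_bp` (120) is a
passing window, and overlapping passing windows are merged. Merging makes the
output deterministic and parameter-free where several windows overlap; a
merged region can therefore span more than 120 bp while every CpG in it
belongs to at least one qualifying 120-bp window.

Coordinates are 0-based half-open (BED). A CpG position is the plus-strand C
of the strand-collapsed dinucleotide; a region covering CpGs p₁…p_k spans
[p₁, p_k + 2). Cross-tissue validation is the same criterion applied to any
additional methylomes via `audit_regions` + `filter_cross_reactive`: a hypo
region is dropped if any non-target cell type's regional mean β falls below
`hi`. The audit never suppresses regions that are low in two cell types — it
exists precisely to expose markers (such as erythroid loci that are also
unmethylated in megakaryocytes) that cannot separate related lineages.

## Molecule classification and GE/ml

Each targeted bisulfite amplicon molecule yields one call per CpG: M (read
CG), U (read TG) or N (no call). A molecule is counted as derived from the
marker's target cell type when all CpGs are unmethylated, tolerating up to
`max_methylated` exceptions — 0 for erythroblast-type markers, 1 for
megakaryocyte-type markers. The tolerance is a fixed per-panel property, not
scaled with amplicon CpG count and not inferred from data. Molecules with
any N call are excluded from numerator and denominator (default): the rule
quantifies over all CpGs of the fragment, and a partial read is ambiguous.
The per-marker fraction is unmethylated / non-excluded molecules; zero
non-excluded molecules gives a missing value, never 0. Fractions resting on
fewer than `min_reads = 30` molecules are flagged low-confidence but
reported; the cutoff is a pragmatic default, 30 molecules bound the binomial
standard error of a small fraction at roughly ±0.09.

Bisulfite conversion is audited at non-CpG cytosines (unmethylated in human
DNA, so full conversion must read them as T): the sample-level rate is
1 − Σunconverted/Σtotal pooled over reads, with a default pass threshold of
0.98 — samples failing it are flagged, not dropped.

Cross-marker aggregation to one per-cell-type fraction is not specified by
the assay description; the default is the read-depth-weighted mean over
markers (equivalent to pooling molecules when amplicons share the
classification rule), with unweighted mean and median as options, and the
method recorded in the output.

The concentration conversion uses the printed constant 303 (ng/ml →
haploid GE/ml; haploid genome mass 3.3 pg) for reproducibility of the
published arithmetic; the unrounded 1000/3.3 = 303.0303… is available as
`GE_PER_NG_EXACT`.

## Deconvolution

The observation unit is a *homogeneous block*: a run of nearby CpGs whose
methylation is near-constant within every reference sample. The segmenter is
a deliberately simple greedy scan — a CpG (covered in all samples) joins the
current block iff its distance to the previous CpG is ≤ `max_gap_bp` (500)
and, in every sample, |β − running block mean| ≤ `tol` (0.25). The published
analyses used an external multi-sample segmentation tool; reproducing its
algorithm is out of scope here, blocks are equally accepted as a BED-like
table, and the downstream NNLS is agnostic to the segmenter.

Mixture proportions solve min‖Ax − b‖₂ subject to x ≥ 0 over the blocks the
sample covers (NaN marks uncovered blocks), using scipy's active-set NNLS;
KKT conditions of the solution are asserted in the test suite. The solution
is renormalized to the unit simplex *after* solving — the common formulation
in reference-based methylome deconvolution — and the residual is reported on
the unnormalized fit. Uninformative blocks (identical across cell types) are
dropped at atlas construction; whether the original analysis filtered them
or weighted blocks by coverage is unknown, and neither weighting is applied
by default. Samples covering fewer blocks than cell types, or a
rank-deficient covered atlas, return a result flagged `unidentifiable`
rather than a silent answer.

Confidence intervals bootstrap **blocks** with replacement (the unit the
deconvolution observes), re-solving per replicate: default 10,000
iterations, 90% level, empirical quantile CIs, point estimate = mean across
replicates, rank-deficient replicates redrawn. A read-level bootstrap was
not added: read-resampling uncertainty belongs to the targeted module's
binomial fractions, not to the block-level fit.

## Platelet composition arithmetic

Chromosome representation compares observed read fractions with
reference-length-derived expectations from a user-supplied chrom.sizes table
(no genome build is hard-coded; Y is excluded by configuration for female
samples). Counts are consumed as a post-alignment, post-dedup table;
filtering is upstream. Enrichment is observed/expected, and the
expected-weighted mean enrichment is 1 by construction.

Per-platelet content: genomes/platelet = (DNA mass in pg / 3.3 pg) /
platelet count; genomic kb/platelet = m·16.569 kb·(1 − f)/f for m
mitochondrial genomes per platelet (default 5) and measured mitochondrial
DNA fraction f. At f = 0.59 the defaults give ≈ 57.6 kb — treated as an
order-of-magnitude consistency check (the published "~56 kb" arithmetic is
not shown), not an exact target.

The transfusion chimerism ratio is the raw SRY/control count ratio by
default, with a ×2 copy-number correction (single-copy SRY vs two-copy
autosomal control) behind a flag, since the published ratio is
count-derived without a stated correction. Each timepoint also reports its
detection limit 1/control-count; zero-control timepoints are flagged, never
dropped.

## Statistics

Group comparisons use the two-tailed Mann-Whitney U test: exact by
enumeration when n₁ + n₂ ≤ 20 and the pooled data are tie-free, otherwise
the tie-corrected normal approximation (both via scipy, validated against a
brute-force rank-split enumeration in the tests). Quartiles use linear
interpolation; whisker fences sit at 1.5×IQR beyond the quartiles; values
beyond the fences are flagged as Tukey-convention outliers but never
excluded automatically — the original outlier-exclusion rule is unspecified,
so exclusion requires an explicit user action on the flag list. No
multiple-testing correction is applied by default (raw p < 0.05 is the
reported convention); Holm step-down is available via flag.

## Synthetic-data regimes

All generators are pure functions of (config, seed) with a single explicit
`numpy.random.Generator` stream; identical inputs give byte-identical
outputs.

**Atlas.** Background CpGs sit at β = 0.85 (a methylated genome-wide
baseline); planted marker regions are driven to 0.03 in the target and 0.97
elsewhere (inside the < 0.05 / > 0.95 planting regime), with 5 CpGs spaced
25 bp so each planted region fits one 120-bp window, and ≥ 6 background CpGs
between regions so recovered regions cannot bridge. Observed β values are
beta-binomial: a per-sample, per-site level drawn from a beta distribution
with concentration `beta_noise` around the configured mean, then binomial
counting at the configured depth. The noisy regime uses concentration 300
(per-site sd ≈ 0.01 at marker-grade extremes), reflecting the high replicate
concordance of WGBS on purified cell populations; at 30× depth the counting
noise (sd ≈ 0.03 at β = 0.03) dominates this biological layer.

**Amplicon reads.** Each molecule is target-derived (all U) with probability
`true_fraction`, else background (all M). Conversion failure flips U→M per
CpG independently (default 0.005, i.e. 99.5% conversion — typical of
commercial bisulfite kits); sequencing/basecall error flips calls
symmetrically at 0.001; non-CpG cytosine counts (8 per read) are drawn
binomially at the conversion failure rate, so conversion QC sees the same
process. Per-CpG independence is the simplest defensible failure model; no
model is published.

**Cohorts.** Group mean GE/ml defaults are the observed clinical regimes:
healthy 510, ITP 1608, ET 4242, hypoplastic marrow 250 for the MK panel
(n = 77/5/5/5), and healthy 7 vs thalassemia 1658 for the erythroblast panel
(n = 77/3). Between-individual variability is log-normal with σ = 0.25
(arithmetic mean preserved) — moderate biological variability chosen a
priori; group-level total-cfDNA means (healthy 10, ITP 20, ET 35,
hypoplastic 10, thalassemia 20 ng/ml, σ = 0.20) encode the elevated cfDNA of
high-turnover states and keep every group's implied unmethylated fraction
well below 1 (a config implying fraction > 1 is rejected; individual draws
above 0.98 are redrawn). Panels use 4 markers × 5 CpGs × 2000 reads per
marker.

**WGBS counts.** Multinomial over chromosomes: 59% mitochondrial, the
remainder length-proportional over human-like chromosome sizes with skew
multipliers (chr4 ×1.3, chr17 ×0.7) mimicking the observed non-random
autosomal representation of platelet DNA.

**What passing tests show.** The generators emulate the *statistical*
structure of the assays (mixture fractions, counting noise, conversion
failure, group-level dispersion) but not alignment artifacts, fragment-length
biology, PCR duplicates, inter-marker efficiency differences, or real
inter-individual methylation heterogeneity. Recovery of planted truth
therefore validates the estimators and their calibration, not the wet-lab
performance of any particular marker panel on real plasma.

## Problem sizes and numerical choices

The acceptance script and test suite run marker discovery on a 100,000-CpG
atlas (5 cell types × 2 samples, 50 MK + 200 erythroblast planted regions),
NNLS calibration on a 50-block × 3-cell-type atlas (100 error replicates;
200 coverage simulations × 400 bootstrap iterations, a resolution at which
empirical 90% quantiles are stable), and cohort recovery at the full default
cohort sizes — sizes chosen so the whole suite runs in well under a minute
while keeping Monte-Carlo error small relative to the tolerances tested.
Simplex renormalization tolerance is 1e-12; noiseless recovery is asserted
at 1e-6 against truth and against an exhaustive simplex grid-search oracle;
bootstrap replicates that are rank-deficient are redrawn up to 100 times
before erroring.

## Known limitations

- The greedy segmenter is a stand-in contract, not a reimplementation of
  the published multi-sample block segmentation; block boundaries will
  differ from external tools (downstream NNLS accepts external blocks).
- Exact Mann-Whitney enumeration is limited to tie-free pooled samples of
  ≤ 20; ties always route to the corrected approximation.
- `aggregate_cell_type` offers three conventions because the published
  per-cell-type summary is ambiguous; results at very uneven marker depths
  depend on the choice.
- GE/ml inherits any bias in the fluorometric cfDNA concentration; the
  constant 303 assumes fully double-stranded, intact haploid genome mass.
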