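# Methods

This note documents the models, defaults and numerical choices behind
`magic_ratoon`, and what the synthetic data generator does and does not
emulate.

## Population simulator

**Design.** Eight homozygous founders are combined through a fixed funnel:
four two-way crosses (DA5×Pra, ZS97×MH63, YJSM×IR34, GC2×Cypress), two
four-way crosses pairing the two-way families, and 144 eight-way F1
families from pairwise crosses of the two four-way families.  Four F2
plants per family are advanced by single-seed descent (default five
generations, giving F7), and 302 of the 576 candidate lines are selected
uniformly at random.  Selection by heading date is not modelled
genetically; the three staggered sowing batches are represented only as a
fixed covariate.

**Meiosis.** Haldane model: per gamete and chromosome the crossover count
is Poisson with mean `L_cM / 100`, positions uniform in physical
coordinates (uniform cM/bp), no interference.  This is the simplest model
consistent with the study design and makes closed-form checks available:
with recombination off every chromosome descends intact from one founder,
and residual heterozygosity decays as `het_F2 · 0.5^g` over `g` SSD
generations, where `het_F2` has a closed form from the founder quartets
(`simulate.expected_f2_het`).  Because heterozygous stretches come in
tracts, tolerance in the decay tests is based on the per-line spread
(lines are independent replicates), not on a site-level binomial.

**Genome.** Default 12 chromosomes, 30 Mb / 150 cM each, 2,000 sites per
chromosome.  Sites are placed in clusters of 4 within 2 kb windows
("gene-like loci") spread evenly along the chromosome; synthetic gene
models are carved from these clusters.  Clustered placement keeps genes
genetically tiny (~0.01 cM), so within-gene recombinants are rare and the
founder-mosaic oracle — every common gene haplotype equals a founder
vector — holds for testable classes; the occasional recombinant chimera
lands in the RARE bucket (below `min_class_size`) by construction of the
pedigree (a recombinant gamete is shared by at most one family's four
lines).  Every site is polymorphic among the founders with the minor
allele in 1–4 founders; a configurable fraction of sites are short indels.

**Phenotypes.** For each trait and season, the line-level value is a sum of
standardized components scaled by target variance fractions: planted QTLs
(founder allelic series at real panel sites; the line value is the mean of
its two homolog founders' effects), a cross-season shared polygenic term, a
season-specific polygenic term, a sowing-batch offset, and per-replicate
noise.  Polygenic terms are built from random weights over 200 background
sites so they carry genuine kinship structure.  Because population
structure makes nominally independent draws correlate, each polygenic draw
is orthogonalized in-sample against the trait's other components before
scaling; planted fractions are therefore realized almost exactly, which is
what the recovery tests rely on.  Phenotypes are mapped to trait scales via
per-season means and SDs patterned on field values reported for such populations (e.g. main-crop
TN mean 12.6, ratoon TN mean 16.4); a positivity floor at 1% of the mean
guards count/length scales and deactivates on centered test architectures.

Grain yield is by default *composed* from the standardized TN/SPP/PL
line-season values with season weights (MC: 0.45/0.28/0.10, RC:
0.55/0.31/0.16) plus independent noise, chosen so the standardized
regression ordering matches the reported pattern (TN > SPP in the main crop;
TN > SPP > PL in the ratoon crop); a `direct` mode simulates GY from its
own spec instead.  The default architecture plants QTL effects in the
5–24% PVE range, including a panicle-length locus active in both seasons
(PVE 0.20 / 0.11), a tiller-number locus with opposite-sign effects across
seasons (the signature pattern of a shared PL/TN region with season-antagonistic tiller effects), and a
three-allele series detectable mainly by the gene-based scan.  The PL
cross-season correlation target is 0.67, assembled from the shared
polygenic fraction, the batch fraction, and the geometric-mean contribution
of season-shared QTLs (`TraitSpec.expected_cross_season_r`).

**What the generator does not emulate:** sequencing reads, alignment and
variant-calling error processes (site QC annotations are drawn directly in
passing or failing ranges), genotype missingness (off by default), linkage
phases of heterozygous sites, heading-date genetics, and field spatial
trends.  Passing tests therefore demonstrate correctness of the analysis
machinery under the assumed statistical structure, not robustness to raw
sequencing artifacts.

## Variant QC

A site is retained iff QD > 1, MQ > 40, FS < 80, MAF ≥ 0.05, missing rate
< 0.8, heterozygous rate < 0.05 and mean depth strictly between 2 and 15
(all configurable).  Two readings deserve note: the MAF rule is implemented
as *retain MAF ≥ 0.05* (the standard high-quality-site reading), and the
missing-rate bound is kept at the literal 0.8 (plausible at ~5× coverage);
whether that bound was meant as 0.2 is reachable via configuration.  Absent
INFO fields pass their criterion and are logged.  Multi-allelic records are
split into per-ALT pseudo-sites with other ALTs folded into REF, matching
the downstream biallelic tests.  The filter is a pure per-site predicate —
idempotent, order-independent, and monotone in each threshold — and the
report attributes each removal to the first failing criterion in the fixed
order qd, mq, fs, maf, missing, het, depth.

## Gene haplotypes

A gene's marker is the concatenation of a line's alleles at retained
SNPs/indels whose POS falls in the gene's CDS intervals (1-based
inclusive; indels judged by POS only, matching VCF left-alignment).  F7
lines are near-homozygous, so no phasing is attempted: lines heterozygous
at any coding site are set to MISSING by default (an `allele` policy that
treats a het call as its own symbol is available), as are lines with
missing calls.  Classes are labelled Hap1..HapK by descending frequency
with a lexicographic tiebreak; classes below `min_class_size` (default 10
lines, ~3% — small enough to keep classes of ~19–21 lines like those the published
effect tables retain) merge into RARE, which is reported but untested.
Dummy coding uses (K−1) indicators against the most frequent class.
Strand never affects haplotype identity.

## Mixed-model association

**Kinship.** Default `allele_sharing`: `K_ij = 1 − d_ij`, `d_ij` the mean
per-site nucleotide difference fraction (|dosage difference|/2) over
jointly called sites — the most direct operationalization of kinship from
nucleotide diversities; a VanRaden centered GRM is available.  The matrix
is bent to PSD by flooring negative eigenvalues at zero (the pre-bend
minimum eigenvalue is recorded).

**REML.** The null model is fit by profiling the restricted likelihood of
`delta = sigma_e^2 / sigma_g^2` on the spectral decomposition of K: a
121-point log grid over [1e−5, 1e5] followed by bounded scalar refinement
(xatol 1e−10), which is deterministic and robust to the likelihood's
occasional flatness (at K = I it is exactly flat in delta and only the
total variance is identified, matching the OLS residual variance).  The
spectral form is verified against a dense matrix evaluation to 1e−8.

**Scans.** Default P3D/EMMAX: marker tests are GLS F-tests with the null
variance fixed, computed for complete markers by rotating once and
residualizing against the covariates (vectorized over markers); markers
with missing genotypes drop those lines and fall back to a Cholesky GLS on
the subset; an `exact` mode re-optimizes delta per marker.  Gene tests are
joint (K−1)-df F-tests on the haplotype dummies under the same variance;
genes with fewer than two testable classes or rank-deficient designs after
masking are skipped and logged.  Residual degrees of freedom are
`n − rank(W) − df_test` (standard EMMAX practice).  PVE comes from an OLS
refit (difference in R² over the covariates), clamped to [0, 100].

**Thresholds.** `alpha / Meff` with the Li–Ji eigenvalue method: within
each chromosome the marker (or gene-score) correlation matrix is processed
in consecutive blocks of `window` markers (default 200, a tractability
choice) and block contributions `sum(I(λ≥1) + frac(λ))` are added within
and across chromosomes.  Monomorphic markers carry no test.  The printed
thresholds are reported to two significant figures; with the published
effective test numbers (15,948 SNP-based; 3,693 gene-based) the
arithmetic reproduces 3.1e−6 and 1.4e−5.  Those Meff values are treated as
reference inputs for the threshold arithmetic, not as reproducible outputs
— the exact Meff algorithm and kinship estimator behind those published
numbers are unstated, so both are configurable here and only the
alpha/Meff arithmetic itself is treated as checkable.

**Calibration.** On pure-noise phenotypes over the simulated kinship the
type-I error at p < 0.05 stays within 0.05 ± 0.01 aggregated over seeds,
and the genomic-control lambda is checked as an aggregate over seeds
(individual 2,000-marker scans carry ~±0.1 of LD-induced sampling spread
around 1).

## Trait statistics

* **RA** = ratoon TN / main TN on line means; undefined (NaN, flagged) for
  non-positive main-crop TN; scale-invariant.
* **Cross-season correlations** are Pearson r on line means with t-based
  p-values.
* **Yield-component regression** standardizes GY, TN, SPP, PL to unit
  variance and fits OLS (statsmodels), reporting standardized betas and
  p-values; a condition-number warning flags collinearity.
* **ANOVA** is the sequential (type-I) two-way partition on per-replicate
  records with factors line, season, line×season, computed by explicit
  balanced projections (fast for hundreds of line levels); percent
  components sum to 100 by construction, tiny negative sequential
  interaction terms from imbalance are clipped and renormalized with a
  warning.  With a single replicate the interaction is confounded with the
  residual and the partition degrades to three terms, flagged.
* **Heritability** uses the mean-squares method: `Vg = (MS_G − MS_GxE)/(rs)`,
  `V_GxE = (MS_GxE − MS_e)/r`, `Ve = MS_e`, negative estimates floored at
  zero, and `h² = Vg / (Vg + V_GxE + Ve)`.  Note `Vg` is the cross-season
  covariance of line effects — season-specific genetic variance is
  interaction, not `Vg`.  The published heritabilities are not
  exactly derivable from the published percent components; this package
  defines h² from the variance components and leaves that discrepancy
  unreconciled.
* **Duncan's multiple range test** computes least significant ranges from
  `scipy.stats.studentized_range` quantiles (numeric inversion, arbitrary
  error df — no hard-coded tables) at the protection level
  `alpha_p = 1 − (1−alpha)^(p−1)`, with the harmonic mean of class sizes
  for unbalanced data (Kramer adjustment, as common `duncan.test`
  implementations use).  Spans below their LSR protect all nested
  sub-spans; letters are emitted from maximal non-significant intervals,
  'a' at the highest mean.  Under the null the familywise separation rate
  is α for two classes and slightly above α for k ≥ 3 — an inherent
  property of Duncan's protection level, reflected in the test bands.
* **Haplotype effect tables** report mean ± SD, n, Duncan letters and the
  difference to a reference class per trait × season plus RA.  The
  reference defaults to the class carrying the most founders (the
  convention reconstructed from the published tables' arithmetic), else the
  most frequent class; both are configurable per gene.

## QTL reporting

Significant markers cluster per chromosome by single-linkage within a
500 kb merge window — a reporting convention, since no clustering rule is
part of the association model.  SNP and gene clusters with peaks within
the window are reported as one QTL carrying both peaks (method provenance
is always kept; methods are never required to agree).  Names follow
`q<TRAIT><chrom>[.i]` with sub-indexes in ascending genomic order within a
trait-chromosome across seasons.  Landmark annotation takes a BED file
(0-based half-open) and reports the signed distance from the peak to the
nearest interval (0 inside).

## Pipeline and problem sizes

`run_pipeline` chains simulate → qc → haplotype → gwas → stats → report,
writing TSV/JSON artifacts and a manifest with SHA-256 hashes; a fixed
seed reproduces the manifest exactly.  The simulate, qc and haplotype
stages skip work when their outputs exist, so deleting a downstream file
regenerates only that stage; the scan stages recompute in memory and
rewrite only missing files.  GWAS phenotypes are line means within season
(no replicate-combination rule is prescribed; per-replicate
records remain available in the phenotype table), with batch dummies as
fixed covariates.

The test suite runs desk-scale versions of every check: funnels of 30–144
families, genomes of 2–4 chromosomes with 120–500 sites each, 60–302
lines, 20-seed power/PVE replicates and 10-seed calibration scans.  These
sizes were chosen to keep the full suite in the low minutes while leaving
every statistical tolerance meaningful at the stated n.
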