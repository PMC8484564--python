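# Methods

This note documents the models, algorithms, defaults and design choices
behind `heatgs`, and what its simulation-based tests do and do not
establish about real data.

## Study design being modeled

The package targets the genomic-selection loop of a biparental selfing
program: a heat-tolerant hybrid founder is selfed from F2 onward by
single seed descent (SSD, one seed per line per generation, no
selection); one generation (F4 by convention) is phenotyped and GBS
-genotyped to train a prediction model; the model scores the next,
unphenotyped generation (F5); selections are validated in the offspring
generation (F6). Two negatively correlated traits — yield per plant
(YP, kg) and soluble solid content (SSC, °Brix) — are the canonical
trait pair.

## Population simulator (`simpop`)

Meiosis. Crossovers are a Poisson process on the centiMorgan scale
(rate 1 per Morgan, uniform placement, no interference); the gamete's
starting haplotype is a fair coin. Marker positions are uniform on each
chromosome. The Kosambi function is used wherever a map distance must be
converted to a recombination fraction (r = ½·tanh(2d)); crossover
placement itself is interference-free, the standard default when no
interference model is specified.

SSD bookkeeping. F1 is heterozygous everywhere. Each F2 line comes
from two independent F1 gametes; each subsequent generation advances
every line by one selfed seed. Expected residual heterozygosity at F(t)
is (1/2)^(t−1), which the tests verify by Monte-Carlo.

Traits. Additive QTL are placed at a random subset of markers, shared
between traits. Effects are drawn from a correlated bivariate normal and
then aligned exactly: the second trait's effect vector is recombined
(Gram–Schmidt in genetic-value space, which is linear in effects) so the
in-sample genetic correlation with the lead trait equals `rho_g`
precisely (default −0.33). Without this alignment the realized
correlation of a single population scatters widely (20 linked QTL give
draws anywhere in ±0.3 of the target, occasionally sign-flipped), which
would make every correlation-dependent test flaky; planting the
correlation is therefore treated as part of the study conditions.
Effect scaling is fixed once, at the first generation phenotyped, so F4,
F5 and F6 share one architecture; phenotypes are y = g + e with
var(g) = h²·sd² and var(e) = (1−h²)·sd² on the trait scale (defaults:
YP mean 8.0 sd 3.0, SSC mean 4.4 sd 0.8, h² = 0.6). Ordinal scores
(1–5 scale traits) cut the latent phenotype at its quintiles. Dominance
is off by default (an optional coefficient applies at heterozygous loci).

GBS artifacts. Per-marker missing rates are Beta(2, 8) (mean 0.2);
the rate is a property of the marker (it mimics restriction-site
coverage), so different generations masked from the same configuration
share a rate profile and their call-rate-filtered marker sets overlap
heavily, as in real GBS series. A configurable fraction of markers
(default 5%) is replaced by a low-MAF spectrum tail (minor-allele
frequency uniform on [maf_floor, 0.05]) so the MAF filter has realistic
work to do; these columns mimic calling artifacts and are deliberately
not linkage-coherent, and QTL are never placed on them.

What the simulator does not emulate: read-level sequencing error,
depth-dependent genotype quality, segregation distortion, residual
heterozygosity selection, or LD decay calibrated to a real genome.
Passing tests therefore demonstrate correctness of the algorithms under
the stated generative model, not field-data performance.

## Marker QC (`variantio`)

Dosage coding is −1/0/+1 (hom-ref/het/hom-alt), NaN for missing. The
MAF filter removes markers with minor-allele frequency strictly below
the cutoff (default 0.05; a marker exactly at the cutoff survives, with
a 1e−9 float guard at the boundary). The PEMV filter keeps markers
genotyped in at least x% of lines — vcftools-style `max-missing`
semantics, so higher PEMV keeps fewer markers. H is observed
heterozygosity (fraction of heterozygous calls among non-missing); PIC
uses the biallelic Botstein form 1 − (p²+q²) − 2p²q². Transitions are
A↔G and C↔T. Density windows are half-open, 1-based. Phenotype
summaries use pairwise-complete Pearson correlations with a Bonferroni
factor equal to the number of trait pairs.

## EM imputation (`impute`)

Model: each marker column is a draw from N(μⱼ·1, Σ) with a shared
line-by-line covariance Σ (the realized-relationship structure). The
E-step replaces missing calls by their conditional means given observed
calls of related lines (computed from Σ⁻¹ per missingness pattern, with
the conditional covariance accumulated); the CM-steps re-estimate μⱼ by
GLS and Σ from completed data.

Column centering makes the centered rows sum to zero exactly — a rank
deficiency the unregularized EM exploits, imputing from the sum-to-zero
constraint instead of relatedness. Σ is therefore estimated with a fixed
inverse-Wishart-style prior (scale 0.05 × mean line variance), i.e.
MAP-EM; the reported per-iteration objective is the corresponding
penalized log-likelihood, which is non-decreasing and is asserted as
such in the tests. Defaults: tol 1e−4 on the largest imputed-value
change, max 100 iterations, deterministic initialization at column
means. Imputed dosages stay fractional (ridge regression consumes
continuous covariates) and are clipped to [−1, 1]. Column-mean
imputation is available as `method="mean"`.

## RR-BLUP (`rrblup`)

y = 1μ + Zu + e with i.i.d. normal marker effects. REML (default; ML
optional) profiles λ = σ²ₑ/σ²ᵤ after projecting out the intercept with
an orthonormal complement basis and one eigendecomposition of the
projected kernel — O(n³) in lines, independent of marker count, the
right trade-off for ~100 lines × ~10⁴ markers. λ is maximized on an
81-point log grid on [1e−6, 1e6] refined by bounded Brent search; when
the optimum pins to the upper bound σ²ᵤ is set to 0 (no usable genetic
variance) with û = 0. Dosages are not column-standardized by default
(raw marker-effect model); standardization is a flag. The reported h²
is σ²ᵤ·tr(SKS)/(n−1) over itself plus σ²ₑ, i.e. on the genomic-value
scale. GEBVs are exposed both centered (Z·û) and with the intercept
added, since selection thresholds may be quoted on the absolute trait
scale.

## Hold-out grid and selection (`gsopt`)

For each PEMV level the training population is filtered once
(MAF + call rate) and EM-imputed once; the marker kernel is precomputed
so each of the n_iter hold-out draws only refits variance components on
the training subset of the kernel (test sets are drawn independently per
iteration — repeated hold-out, not a partition). Each grid cell has its
own child seed, making the whole grid bit-reproducible. The best cell is
the highest mean accuracy; ties break toward larger training sets, then
higher PEMV.

Cross-generation prediction intersects marker sets on (chrom, pos) with
allele-pair reconciliation (swapped ref/alt markers are kept with dosage
sign-flipped). Candidates are labeled best when GEBV strictly exceeds
the reference genotype's GEBV (the founder hybrid, heterozygous
everywhere in simulated runs); a selection is confirmed when the line
was predicted best and its offspring phenotype strictly exceeds the
reference phenotype.

## Variant annotation (`annot`)

A deliberately small rule engine over GFF3 gene models and a FASTA
genome: CDS variants are translated strand- and phase-aware (standard
code) into synonymous/missense/stop_gained/stop_lost/start_lost; the
first 2 intronic bases at a junction are splice_donor/acceptor
(transcription-direction aware), 3–8 bases are splice_region; exonic
non-CDS positions are 5'/3'UTR by position relative to the CDS span;
within `updown_bp` (default 5000) of the transcript span is
upstream/downstream; otherwise intergenic. One class per variant: the
most severe across overlapping transcripts, with a fixed severity order
and the conventional impact mapping (HIGH for stop/start/splice-site
changes, MODERATE for missense, LOW for synonymous/splice_region,
MODIFIER otherwise). Transcripts whose CDS length is not a codon
multiple after phase adjustment are flagged and fall back to non-coding
classes. "Gene body" panels keep every non-intergenic SNP (UTR,
up/downstream, intron and coding classes together); a size-matched
random panel (fixed seed) is the control.

It is not a full annotator: no regulatory features, no INDEL
consequences, no isoform-expression weighting.

`synthetic_reference` writes a synthetic genome + gene models consistent
with a simulated marker set (reference alleles planted into random
sequence; two-exon phase-0 genes tiled so that gene bodies plus flanks
cover ~20% of the genome). It is a labeled synthetic stand-in for a real
assembly, used only to exercise the annotation stage of simulated runs.

## QTL mapping (`qtlmap`)

Lines are coded and modeled as an F2 cross (AA/AB/BB), as is
conventional when later selfing generations are analyzed with F2
machinery; the reduced heterozygosity of F4+ data enters through the
data, not the model.

Map estimation: adjacent-marker recombination fractions by maximum
likelihood on the 3×3 two-locus genotype counts (coupling-phase F2
table), capped at 0.4999, converted to cM by the inverse Kosambi
function and accumulated. Scans: an HMM over the genotype chain
(transition matrices from the map function, emissions with a
genotyping-error probability of 1e−4 — without it, apparent double
recombinants in selfed-generation data are impossible under a tight F2
chain and zero out the forward pass) yields genotype probabilities on a
grid of step 1 cM (marker positions are always included in the grid).
At each position a three-component normal mixture is fitted by EM
(tolerance 1e−6 on the log-likelihood, max 1000 iterations; Haley-Knott
start); LOD = (LL₁ − LL₀)/ln 10, which reduces exactly to the
(n/2)·log₁₀(RSS₀/RSS₁) regression LOD at fully observed markers.

CIM adds up to `n_marcovar` (default 4) background marker covariates
chosen by greedy forward selection on the trait (largest squared partial
correlation, residualizing after each pick; missing covariate calls are
mean-filled); covariates within `window_cM` (default 15) of the scan
position are dropped there. With zero covariates CIM is identical to
SIM by construction.

Permutation thresholds shuffle the trait vector n_perm times (fixed
seed) and take the (1−α) quantile of the genome-wide maximum LOD. The
vectorized scan engine iterates EM per (trait, position) cell with an
active-set convergence test, so permutation batches stay cheap. Variance
explained is h² = 1 − 10^(−2·LOD/n). Bayes credible intervals normalize
10^LOD over a chromosome's grid, grow the smallest contiguous region
around the peak to the target mass (0.95), and expand outward to the
nearest flanking markers; a flat curve yields the whole chromosome with
a warning.

## Pipeline (`pipeline`)

`run_study` chains the stages (simulate-or-ingest → QC → grid per trait
→ best-cell fit → cross-generation intersection and prediction →
selection → offspring validation → annotation → full/genic/random panel
retraining at the best cell → map estimation, CIM scan and permutation
threshold) and records a manifest: configuration hash, per-stage record
counts, result summaries, timings and output sizes. The manifest hash
covers configuration, counts and results (not timings), so a fixed
configuration reproduces it bit-for-bit. A single master seed is
expanded into fixed per-stage child seeds so stages can be re-run
independently. Any stage failure raises with the stage name and the
manifest accumulated so far.

## Problem sizes

Defaults mirror the study scale at desk cost: 12 chromosomes × 120 cM,
3000 markers, 100 lines. The test suite and the acceptance script use
reduced sizes chosen as the package's own desk-scale conditions:
heritability recovery on 50 populations of 300 lines × 500 markers; the
5 × 5 hold-out grid at 100 iterations on 100 lines × 900 markers;
permutation calibration on 4 chromosomes × 80 cM × 100 markers with 200
permutations, 200 null replicate genomes and 50 localization replicates;
the simulated end-to-end study on 6 chromosomes × 900 markers. Scan
steps of 1–2 cM are used in place of denser grids.

## Known limitations

* The F2 coding of F4+ lines inflates apparent map lengths (extra
  effective meioses); map-recovery checks are run on F2 data where the
  coding is exact.
* EM imputation assumes a shared Gaussian line covariance; it is not a
  haplotype- or pedigree-aware imputer.
* The hold-out grid refits variance components every iteration; with
  very small training sets REML occasionally pins to a variance
  boundary, which simply yields a zero-effect model for that draw.
* Composite interval mapping loops over scan positions in Python; for
  dense grids with many covariates SIM-based permutations are the
  intended fast path for thresholds.
* The annotator resolves one consequence per variant (most severe
  transcript); per-transcript reporting is out of scope.
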