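# Methods

`epicanal` re-implements, as a tested library, the integrative analysis of
genome-wide CG-methylation loss across a panel of *Arabidopsis thaliana*
accessions: negative-binomial differential expression under an interaction
design, region-level methylation quantification with a simplified
differentially-methylated-region (DMR) caller, differential
chromatin-accessibility selection, cross-accession canalization statistics,
epigenetic-state gene classification, and amplicon-based segregation
genotyping.  Because the original measurements require hundreds of plant
sequencing libraries, every stage is exercised end to end on synthetic data
with planted ground truth; this note records the models, the parameters
that matter, and the design choices that were genuinely open.

## The synthetic panel

The generator emulates a knockout of the CG maintenance methyltransferase
(MET1 in *A. thaliana*) across 18 accessions.  Each accession carries one
wild-type line and two independently derived mutant lines with three
biological replicates (162 RNA/ATAC samples at the defaults).  Mutant
lines are first-generation homozygotes except that two accessions carry a
second-generation homozygous line; bisulfite libraries pool replicate
tissue, so the methylation panel has one sample per line (54 methylomes).

**Gene classes.**  Genes (default 4,000) are assigned to six classes:

| class | fraction | planted behaviour |
|---|---|---|
| TE_UP | 7.7% | silenced baseline (~5 counts), strong activation in mutants: per-gene log2FC ~ U(3, 6) plus per-accession N(0, 1.2), floored at 1 |
| GBM | 5% | well-expressed (~150), gene-body CG methylated, modest downregulation U(−2.5, −1) |
| TEM | 3% | weakly expressed (~4), TE-like body methylation, upregulation U(2, 4) |
| CANALIZED | 10% | identical wild-type means; accession-specific mutant effects N(0, 2) |
| DECANALIZED | 5% | accession-specific wild-type offsets N(0, 2); mutant effects cancel them |
| NULL | 69.3% | no effect |

The TE fraction mirrors a panel in which ~1,678 of ~21,657 analyzed genes
are TE-associated.  The 2:1 ratio of canalized to decanalized genes
reflects the observed excess of mutant-only over wild-type-only
accession-contrast DEGs.  The per-accession spread of TE activation
(SD 1.2 log2 units) encodes the observation that TE genes are upregulated
everywhere but to a considerably different extent in each background —
without that spread the cross-accession coefficient of variation of TE
genes would be *lower* in mutants, contradicting the direction the
analysis is designed to detect.  Baseline means are log-normal
(μ = ln 50, σ = 1.2), counts negative binomial with constant dispersion
0.1, and per-sample library factors U(0.7, 1.4).

**Methylation.**  Each of 2,000 candidate regions (200 bp; 25 CG, 8 CHG,
15 CHH cytosines on a fixed grid) is either a methylation-loss region
(attached to a TE_UP/GBM/TEM gene body; wild-type CG target U(0.75, 0.95)
with per-accession jitter, homozygous-mutant target 0.2%) or a stable
background region (0.2% in both genotypes).  Site coverage is
Poisson(20), methylated reads binomial.  Relative CHG methylation rises
6.8% in first-generation and 40% in second-generation homozygotes; CHH
drops 21%.  With this mix the simulated mutant CG genome mean is 0.2% and
the wild-type mean ~27%, a ~99% drop.  The generator does not model
bisulfite conversion failure, strand-pair collapsing of symmetric CG
sites, or subcontext effects.

**Accessibility.**  One peak per candidate region, negative-binomial
counts around log-normal baselines with 4-fold library-size variation.
Peaks over TE-like loss regions (TE_UP and TEM, not GBM) get their
homozygous-mutant means multiplied by 2 — the direction of the
methylation–accessibility coupling is established, its magnitude is not,
so the multiplier is a configurable convention.  Each library also carries
off-peak reads such that the fraction of reads in peaks spans 0.2–0.31.

**Segregation.**  A gamete carries the mutant allele with probability *b*
independently through both parents, so homozygotes occur at *b*²; the
default *b* range (0.15–0.42 per line) spans homozygote fractions of
roughly 2–18%.  Read totals are Poisson(120), wild-type reads binomial
around the allele dosage with a 1% miscall rate.

All draws flow from a single seed through named independent streams, so
identical configurations give byte-identical outputs regardless of stage
order.

## Differential expression

Size factors are median-of-ratios against the geometric-mean pseudo-gene.
The "transformed counts" used for all downstream expression levels are
log2(count/size factor + 1) — a monotone, variance-compressing stand-in
for a variance-stabilizing transform; consequently every transformed-count
threshold downstream is recomputed as a dataset quantile, never
hard-coded.

The test is a negative-binomial GLM with log link and per-gene
method-of-moments dispersion pooled over design cells (floored at 1e-4,
capped at 50), fitted by IRLS with the fitted mean floored at 0.5 so that
design cells with all-zero counts keep a finite working variance — without
the floor, a single accession whose wild-type replicates are all zero
inflates the Wald standard error of the averaged contrast and masks even
extreme activation.  Two designs are supported: cell means per accession
within one genotype group (accession contrasts compare one accession
against the average of the others), and wild-type cell means plus a
mutant-vs-wild-type effect nested within each accession (the genotype
contrast is one accession's nested effect, or the balanced average over
accessions for the all-mutants-vs-all-wild-types contrast).

Wald p-values use a t reference with residual degrees of freedom rather
than the normal reference: with three samples per cell the plug-in
dispersion has few degrees of freedom, and the normal reference yields a
measured type-I error of 0.126 at nominal 0.05 (3 vs 3, dispersion 0.1),
versus 0.0505 under the t reference; with many residual degrees of freedom
the two coincide.  Calibration holds for base means ≳50; at very low
counts the test is conservative (type-I ~0.008 at mean 5), the usual
discreteness behaviour of count tests.  The package deliberately omits
empirical-Bayes dispersion shrinkage, Cook's-distance outlier handling,
independent filtering, and posterior fold-change shrinkage.

DEGs require padj < 0.01 and |log2FC| > 1 (strict inequalities; an
`inclusive` switch provides the ≥/≤ variant).  Consensus DEGs appear in at
least 2 of the 19 contrasts (18 accession-nested plus the overall one);
universal DEGs in all 19.  Canalization is summarized per gene as the
coefficient of variation (sample SD / mean) of per-accession mean
transformed counts within each genotype group, compared by a one-sided
Wilcoxon rank-sum test with alternative CV(mutant) > CV(wild type);
zero-mean genes are excluded.

## Methylation and DMRs

Region methylation averages 100·meth/total over cytosines of the context
with coverage ≥ 2 reads (per-sample NA when none qualifies); regions with
more than 7 NA samples are dropped — a rule calibrated to a 73-methylome
panel, so other panel sizes should scale it proportionally.  The DMR
caller replaces multi-sample HMM segmentation with a declared two-group
test over caller-supplied candidate regions: at least 10 cytosines,
coverage ≥ 3 per contributing cytosine, and an absolute difference of
group mean percentages ≥ 20.  Group means average per-sample region means
(not pooled reads).  Global context means are unweighted over covered
sites, with an optional coverage-weighted variant.  Interval intersections
use half-open coordinates and a 1 bp minimum overlap.

## Chromatin accessibility

Replicate narrowPeak files are filtered at q ≤ 0.001 on read-in; group
consensus requires base-pair occupancy in ≥ 2 of 3 replicates, union-merged
across groups.  Counts are TMM-normalized (double trim: 30% on M, 5% on A;
reference sample by the upper-quartile-closest-to-mean rule; factors
rescaled to geometric mean 1) and expressed as CPM.  dACR selection is
occupancy- and magnitude-based: stage 1 drops peaks whose two mutant lines
disagree in sign beyond a ±0.25 tolerance in any accession ("similar
accessibility between lines" made operational — the original metric is
unstated); stage 2 requires |Δlog2(CPM+1)| ≥ 1 between mutants and wild
type in ≥ 2 accessions (the magnitude threshold is likewise a declared
convention).  HV-dACRs are the union of two top-quartile CV filters: CV of
the two group means (homozygous mutants vs wild types; with two points the
sample-SD CV is |a−b|/(√2·mean)) and CV over accession × genotype mean
profiles.  HV-dACRs are z-scaled per peak and clustered by k-means
(k = 3, k-means++ with 10 restarts under a fixed seed).

## Integration

Each gene gets strand-aware windows: an extended body from 100 bp upstream
of the TSS to 100 bp downstream of the TTS, and 1.5 kb cis flanks beyond
it, clipped at the chromosome start.  For DMRs, body and flank windows are
kept separate; for accessibility the body and flanks merge into one "cis"
category.  Among features overlapping a window, the one with the largest
absolute per-accession change is assigned (ties to the leftmost start),
and genes are cross-tabulated into both / DMR-only / dACR-only / neither.
Expression change is the difference of mean transformed counts
(homozygous mutants − wild type) per accession.  Wild-type expression and
methylation are binned into quintiles with linear-interpolation percentile
boundaries computed on the full analyzed non-TE gene set (ties to the
lower bin).  Genes with body CG-DMRs are gbM-like when wild-type body
methylation exceeds 80% and expression sits at or above the
40th-percentile boundary (top three quintiles), teM-like when methylation
exceeds 80% and expression sits at or below the 20th-percentile boundary;
the two labels are disjoint by construction.  Metaplots average signal in
10 bp bins over ±1000 bp flanks with the body scaled to 100 bins,
strand-flipped for minus-strand features.

## Genotyping

With r = wild-type reads / total and ≥ 80 reads: homozygous mutant at
r ≤ 0.15, heterozygous at 0.42 ≤ r ≤ 0.58, wild type at r ≥ 0.90, skewed
heterozygous in between; the wild-type rule wins at its boundary.  Lines
segregating a second mutant allele use mirrored categories: the second
allele counts as present above a 10% read fraction, tri-allelic requires
all three alleles ≥ 15%, bi-allelic requires both mutant alleles in the
heterozygous band with wild type ≤ 15% (otherwise skewed bi-allelic or
homozygous for the second allele).  These numeric rules are declared
conventions — the categories exist in practice without published
thresholds — and are configurable.  The per-line report gives genotype
proportions over callable samples; a one-sided exact binomial test of the
homozygote deficit against the Mendelian 1/4 is an extension, off in
strict mode.

## Problem sizes and what passing tests show

The default verification panel (18 accessions, 4,000 genes, 2,000
regions/peaks, 96 progeny per line) was chosen so that the full pipeline
completes in well under a minute on one CPU while every planted effect
class remains recoverable with wide margins.  Passing tests show that the
thresholds act exactly as specified, the numerics match independent
brute-force implementations, and the pipeline recovers effects whose
generative model matches its assumptions (constant dispersion, independent
samples, clean genotype labels).  They do not show robustness to
real-data complications the generator omits: dispersion trends, batch
effects, mapping artifacts, TE mobilization, partial methylation loss, or
segregation of structural variants.

## Known limitations

* Dispersion is method-of-moments per gene with no sharing across genes;
  power at 3 replicates is accordingly lower than shrinkage-based fitters.
* The log2(x+1) transform compresses low-count noise less than a true
  variance-stabilizing transform; CV comparisons at weakly expressed genes
  are noisier than their published analogues.
* The DMR caller tests candidate regions; it cannot discover regions whose
  boundaries differ from the supplied tiling.
* The dACR magnitude threshold and line-consistency tolerance are
  conventions; published dACR counts depend on the original package's
  internal differential test, which is intentionally not re-implemented.
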