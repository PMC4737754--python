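# Methods

`selectscan` re-implements, as a tested library, the analysis chain used in
population-resequencing studies that connect selective sweeps to gene-level
evolutionary rates and DNA methylation: per-site diploid genotype calls plus
outgroup alleles go in; sweep regions, gene-level selection scores, dN/dS
contrasts, metagene methylation profiles, sweep/non-sweep methylation tests
and term-enrichment results with a resampling null come out. Every stage can
also be exercised end-to-end on synthetic data with known ground truth.

## Coordinates and conventions

All internal coordinates are 0-based, half-open. The I/O layer converts at
the boundary: GFF3 and the methylation TSV are 1-based, BED is 0-based
half-open, VCF POS is 1-based. Strand-aware quantities (TSS windows, body
bins, flanks) are computed in transcript orientation and mapped back to
genome coordinates, so "300 bp upstream" means the same thing on both
strands. Genotypes are stored as copies of the non-reference allele (0/1/2,
-1 missing); sites with any missing focal genotype are excluded from spectra
and window statistics so the haploid sample size n stays constant, and every
filter logs its input and surviving counts.

## Polarization and spectra

Ancestral states are assigned by outgroup parsimony: when all non-missing
outgroup alleles agree and match one of the two focal alleles, that allele
is ancestral and the site contributes its derived count; otherwise the site
is retained folded (minor-allele count). The background site frequency
spectrum used by the sweep scan is the chromosome-wide unfolded spectrum
over polarizable segregating sites, normalized over classes 1..n-1 (an
optional pseudocount guards degenerate backgrounds; the default is 0.5 and
matters only for classes never observed on a chromosome).

Diversity statistics are the classical ones: Watterson's theta_W =
S/(a1 L); pi computed from allele counts as sum 2j(n-j)/(n(n-1)) (exactly
the average pairwise difference, in O(S)); Tajima's D with the full 1989
constants, reported as undefined (NaN, not zero) when S < 2. Windows tile
[0, chrom_length) at the step size; a site contributes to every overlapping
window; the trailing partial windows are kept with their true surveyed
length and flagged. Between-population differentiation uses Hudson's FST
with the unbiased per-site numerator/denominator and ratio-of-sums
averaging, chosen for its small sample-size bias; per-site values are also
returned.

## The sweep scan

At each point of a dense grid (default 100 bp) the scan contrasts the
background model -- every site's allele-count class drawn from the
chromosome-wide spectrum phi -- with a hitchhiking alternative. A lineage
at distance d from the swept site escapes the sweep with probability
p_e = 1 - exp(-alpha d). Conditional on k of the n lineages escaping, the
escapees retain their own pre-sweep alleles: a without-replacement draw
from a pre-sweep sample of size n with count j' ~ phi, so the escapee
derived count X is hypergeometric; the n-k hitchhikers all descend from one
additional pre-sweep lineage and are jointly derived with probability
(j'-X)/(n-k). The observed count X + (n-k)B is marginalized over j' and
k ~ Binomial(n, p_e) and conditioned on polymorphism; folded sites sum the
two polarizations. The composite likelihood ratio is
CLR = 2 (l1(alpha_hat) - l0), floored at 0.

Two properties of this construction matter. First, small alpha means
lineages rarely escape even far from the swept site, i.e. a wide, strong
footprint; as alpha grows the footprint shrinks and at the full-escape
limit the alternative equals the background *exactly* (at k = n the
hypergeometric draw returns j' itself). The sweep family therefore nests
the null at the upper alpha boundary, which is what keeps the scan
calibrated: a window whose spectrum matches the background yields CLR = 0,
and on fully neutral simulated genomes the emitted regions cover a few
hundredths of a percent of sequence. An i.i.d. Bernoulli redraw for the
escapees -- a superficially similar operator -- only reaches a binomially
smoothed background, never the background itself; we measured that variant
to inflate neutral excursions several-fold and rejected it.

Numerics: `clr_at_point` evaluates exact per-site distances and maximizes
l1 over log alpha with golden-section search on [1e-7, 1e-1] per bp
(relative tolerance 1e-3). The whole-chromosome scan instead maximizes over
a fixed log-spaced alpha lattice (3 points per decade by default) shared by
all grid points, bins site distances into 64 geometric bins up to the scan
radius (25 kb per side by default; at detectable sweep strengths the escape
probability beyond 25 kb exceeds 0.9), and skips sites with alpha d > 30,
whose likelihood contribution cancels the background term to ~1e-13. These
choices make a 10 x 1 Mb genome scan with ~185k SNPs run in about twenty
seconds on one CPU while tracking the exact path to within a few percent of
CLR -- well below the scale of the ranking decisions the scan feeds.

Post-processing follows the published protocol exactly: targets in the top
1% of CLR genome-wide (cutoff = the ceil(0.01 N)-th largest score, ties
retained; a per-chromosome variant is config-exposed), adjacent selected
grid points merged into regions scored by their summed CLR, regions
strictly larger than 300 bp associated with genes that overlap them or lie
within a 5 kb flank, each gene scored by the maximum summed CLR over its
regions, and the top 3% of all annotated genes reported (ties retained).
"Adjacent" means a gap of exactly one grid step; `max_gap_grid_units`
generalizes.

## Evolutionary rates

dN/dS is estimated by Nei-Gojobori (1986) counting: per-codon
synonymous/nonsynonymous site counts (mutations to stop codons count as
nonsynonymous, so sites per codon sum to 3), differences averaged with
equal weights over all shortest substitution pathways, pathways through
stop codons dropped and codon pairs with no stop-free pathway excluded
entirely, Jukes-Cantor correction d = -3/4 ln(1 - 4p/3) with saturation
flagged at p >= 3/4. Gapped or ambiguous codons are skipped pairwise.
Against Biopython's independent NG86 implementation the estimates agree to
1e-9 on codon pairs where both conventions apply (the implementations
differ, both defensibly, on stop-blocked pathways). A triplet alignment is
summarized by one omega: pairwise dN and dS averaged with the pairwise
site counts as weights, then ratioed -- a counting proxy for a one-ratio
codon-model fit, not a maximum-likelihood tree model. Under the estimator's
own mutation model (equal exchange rates) the median estimate recovers the
generative omega to a few percent at 300-codon genes; under a realistic
transition bias (kappa = 2) NG86 carries its textbook downward bias of
roughly 20% from undercounting synonymous sites, which users should expect
on real data as well.

Rate contrasts use the two-sided Mann-Whitney U-test (exact enumeration
over labelings when the pooled sample has at most 12 values, otherwise the
normal approximation with tie correction); positive-selection enrichment
uses Pearson's chi-square on the 2x2 membership table without continuity
correction (and warns when expected counts drop below 5); site-test
p-values are consumed as input and adjusted by Benjamini-Hochberg at an
FDR of 0.2. Positive-selection flags themselves are never computed here --
codon site models are out of scope.

## Methylation analyses

All analyses use sites covered by at least 10 reads in both tissues. Gene
regions: body = annotated span minus its 5'-most 5%; TSS = 300 bp upstream
to 50 bp downstream of the annotated start; flanks = 10 kb on either side
of the body, truncated (and flagged) at chromosome ends. Region means are
per-gene averages of site-level methylation over covered sites and are
suppressed unless at least 50% of the potential sites in the region are
covered -- "potential" meaning every reported context position, so the
denominator comes from the call files, not from a genome sequence -- with
TSS windows additionally requiring 10 covered sites.

The metagene profile divides each body into 40 length-proportional bins;
the stated 250 bp overlap between neighbouring bins is read as a fixed
+-125 bp extension of each bin core, clipped to the body -- the only
reading that keeps exactly 40 bins for genes of any length. Flanks get
fixed 250 bp bins advancing by 125 bp (79 bins per 10 kb flank). A site is
assigned by its single base position and contributes to every bin whose
extended span covers it. Group curves are means across genes per bin, and
the variance bands are variances across genes (not across sites).

Sweep versus non-sweep contrasts: at the TSS, a two-sided pooled-variance
t-test on per-gene means; elsewhere, a linear mixed model on bin-level
means with sweep status as fixed effect and bin as a random intercept,
fitted by maximum likelihood (not REML, so the likelihood-ratio test
between nested fixed-effect structures is valid), with p from chi-square
with 1 df. The fitter profiles the variance ratio analytically through the
Sherman-Morrison block structure and optimizes one scalar, which makes a
fit essentially instantaneous and, in testing, matches (occasionally
slightly exceeds) statsmodels' MixedLM likelihood. A variance ratio whose
MLE hits zero falls back to the pooled model with a warning. Non-sweep
genes on unplaced scaffolds are excluded from these comparisons, since
scaffolds are never scanned for sweeps. Methylation contexts are collapsed
to CpG versus non-CpG throughout.

Methylation-expression association uses Spearman's rank correlation
(average ranks, t-approximation; exact enumeration for n <= 8). Rate
contrasts across methylation strata compare the upper and lower quartiles
of per-gene region means with the Mann-Whitney machinery above; quartiles
are refused below 8 genes.

## Enrichment

Term enrichment is a two-sided hypergeometric test per term
(minimum-likelihood two-sided mass, direction by comparing the observed
overlap to its expectation, ties called "enriched"), family-wise corrected
by Holm's step-down. The robustness null redraws random gene sets of the
focal set's size from the universe minus the focal genes and reruns the
identical corrected analysis, reporting per term how often it comes out
significant across (by default) 50 sets. The kappa-statistic term-network
grouping of GUI enrichment tools is deliberately not reproduced; flat
per-term testing preserves the statistical core.

## The synthetic-data generator

The generator emulates the study's six input kinds at desk scale with
explicit ground truth; all randomness flows through numpy Generators seeded
as `default_rng([rng_seed, stream])` with one fixed stream per output kind,
so identical parameters give identical files.

Genotypes: a haplotype-free neutral sampler places Poisson(a1 theta L)
segregating sites (the coalescent expectation, so Watterson's estimator is
unbiased for theta) with derived counts from P(j) ~ 1/j and random carrier
assignment. Defaults are the study conditions: 29 diploid individuals,
10 chromosomes of 1 Mb, theta = 0.004/bp (about one SNP per 54 bp), three
sweeps at alpha = 1e-4/bp, two outgroups at 5% divergence and a 1%
polarization error rate. Sweeps apply, to every site within 10/alpha bp of
the center, exactly the escape operator the scanner models: per-lineage
escape with p_e = 1 - exp(-alpha d), escapees keeping their pre-sweep
alleles, hitchhikers copying one random non-escaping lineage. Scan results
on these genomes are therefore a self-consistency check of the estimator,
not a robustness claim; the `mismatched_sweep` mode breaks the symmetry by
replacing part of the footprint with fresh uniform singletons. There is no
linkage outside the sweep operator, no recombination map and no demography;
passing recovery tests says the scan works when its model is right, not
that it is robust to demographic confounding.

Methylome: CpG sites at 0.02/bp (denser inside islands), non-CpG sites as
a sampled subset at 0.05/bp, site levels Beta-distributed (CpG mean ~0.67;
brain non-CpG mean ~0.055; blood non-CpG near zero -- non-CpG methylation
is neuronal), depths Poisson(30), methylated reads Binomial. The CpG
island is the TSS-proximal compartment: 300 bp upstream of the TSS plus
exactly the 5'-most 5% that the body definition excludes, so island and
body are disjoint; island levels are multiplied by 0.15 (the TSS dip). A
latent per-gene propensity shifts both contexts (sd 0.012 CpG, 0.005
non-CpG) and is what expression couples to; sweep genes get additive
offsets of +0.05 (CpG) and -0.02 (non-CpG) on brain levels outside the
island, so the planted body/flank offset is exactly the configured delta.
Expression is log2 FPKM = 6 - 25 x (constitutive body methylation) +
N(0, 0.25): coupling to the *baseline* level rather than the sweep-offset
level encodes the study's control observation that the sweep methylation
contrast is not an expression artifact, and the chosen magnitudes put the
synthetic Spearman correlations at the reported scale (around -0.2 to
-0.4). Codon alignments evolve three taxa from a common root under a
proposal-acceptance process (nucleotide proposals with transition bias
kappa, nonsynonymous acceptances thinned by omega, stops rejected);
kappa = 2 by default. The term map plants one enriched term in a designated
gene set (50% prevalence vs 5% background) among 40 background terms of
uniform prevalence.

## Problem sizes and runtime

The acceptance workload -- simulating and scanning several 10-Mb genomes,
the 200-gene methylome analyses, 300-codon alignments for rate recovery,
and the 50-set enrichment null -- was sized to run on a single CPU: the
full test suite takes about five minutes and `scripts/acceptance.py` about
two. The scan's lattice resolution, distance-bin count and radius are all
config-exposed for users who prefer accuracy over speed.

## Known limitations

No genotype-likelihood machinery (calls are taken at face value; sites with
missing genotypes are dropped, not integrated over); no recombination-aware
background or B-value correction in the scan; NG86 instead of codon-model
ML, with the biases noted above; CHG/CHH contexts collapsed; no
single-site differential methylation; the enrichment module assumes
parent-term propagation was pre-applied to the term map. The simulator's
neutrality is idealized (no linkage, constant population size), so the
scan's false-positive calibration measured here is a best case.
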