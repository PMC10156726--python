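# Methods

`cavepopgen` re-implements, as a tested library, an inference stack for
detecting and classifying repeated evolution across replicate cave/surface
population pairs: summary-statistic scans, sweep-overlap candidate
selection, an eigenanalysis of allele-frequency-change vectors, a
coancestry-based composite-likelihood comparison of convergence modes, two
dating relations, and the downstream enrichment tests.  This note records
the models, the tunable parameters, the numerical choices, and what the
synthetic-data experiments do and do not demonstrate.

## The study design the package assumes

Two lineages of a fish species have each colonized caves independently;
each lineage retains at least one surface population.  The data are
biallelic SNP frequencies per population (from a VCF or a frequency
table), per-population 5-kb sweep classifications (diploS/HIC-style
labels, consumed as input), gene models (GFF3), QTL intervals (BED),
local-ancestry tracts, motif presence/absence tables and GO annotations.

Constants used throughout, with defaults taken from the study system:
recombination rate 1.16 cM/Mb (1.16e-8 Morgans/bp), mutation rate 3.5e-9
per bp per generation, diploid effective size 100,000 for the
composite-likelihood model, 50-kb statistic windows, 50-SNP eigen-scan
windows, 10-kb gene flanks, and a 0.01 empirical significance level.

## Summary statistics and filters

Genotypes pass a four-rule cascade, applied in order and counted once per
site under the first rule that removes it: biallelic SNPs only; more than
20% missing calls within any single population; pooled minor allele
frequency below 1%; and sites where every genotyped sample of some
population is heterozygous (a collapsed-paralog signature).  MAF is pooled
across all samples because a per-population convention is not determined
by the data formats; the choice is recorded here and in the filter report.

Per site, with alternate-allele frequency `p` and haploid sample size `n`:
pi = 2p(1-p)·n/(n-1); Dxy(p1,p2) = p1(1-p2) + p2(1-p1); Fst is the Hudson
(1992) estimator with sample-size correction,
[(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)] / [p1(1-p2) + p2(1-p1)],
aggregated over windows as a ratio of sums.  Missing frequencies are
excluded pairwise per statistic.  Windowed values are means of per-site
values in non-overlapping 50-kb windows; per-gene summaries (min, max,
mean) are computed over the sites inside the gene span, never from window
averages.

Dating: the split time of a cave allele from its surface counterpart is
T = Dxy/(2 mu); the onset of admixture is T_admix = 1/(L_M · p_B), with
L_M the mean minor-parent ancestry-tract length in Morgans and p_B the
major-parent genome fraction.  The ABBA-BABA D statistic is the
frequency-based form with the outgroup defining the ancestral state and a
block jackknife over 500-SNP blocks for its standard error.

## Eigen scan for allele reuse and locus reuse

For k replicate surface→cave pairs, each 50-SNP window yields a k×50
matrix A whose rows are unit-normalized frequency-change vectors.  The
spectrum of C = A·Aᵀ (trace k by construction) classifies the window:

- **allele reuse** — λ1 above the null 99th percentile and every
  eigenvector-1 loading clearly nonzero (|loading| > 0.05) with a common
  sign: all caves moved the same alleles the same way;
- **locus reuse** — the cumulative λ1+λ2 statistic significant, λ2 itself
  above its own marginal 99th percentile, and the sign structure of
  eigenvector 2 (or a sign split of eigenvector 1) partitioning
  replicates exactly by lineage;
- **antiparallel** — λ1 significant with mixed signs not aligned with
  lineage; **divergent** — two-axis significance without a lineage
  partition; **none** otherwise.

The null resamples 10,000 pseudo-windows of 50 SNPs uniformly genome-wide
(same sites across replicates, fresh sites per permutation), which
destroys linkage while preserving the marginal distribution of
frequency changes.  Classification is invariant to replicate order and to
flipping the reference/alternate orientation of any SNP (a column sign
flip leaves A·Aᵀ unchanged).

The marginal-λ2 guard on the locus-reuse call is deliberate.  When two
lineages carry strong but independent signals, the leading eigenvector
concentrates on the larger lineage block while the cross-block coupling
(the random inner product of the two lineage haplotype vectors, of order
1/sqrt(50)) leaks a *coherent* same-sign loading onto the other block; a
plain same-sign rule then miscalls roughly half of such windows as allele
reuse.  Requiring λ2 to be individually extreme before a lineage
partition can be read restores the intended precedence: under true allele
reuse λ2 is noise-level and the guard never fires.

## Composite-likelihood convergence modes

Around each candidate gene (span = gene ± 10 kb), standardized allele
frequencies x = (p - p̄)/sqrt(p̄(1-p̄)) at each SNP are modeled as
multivariate normal with mean zero and covariance F under neutrality,
where F is estimated from intergenic sites thinned to one per 50 kb and
regularized with 1e-6 on the diagonal.  Because standardized vectors are
sum-constrained, one population coordinate is dropped before evaluating
densities.  A composite likelihood sums per-site log densities as if
sites were independent; it ranks models and localizes the selected site,
but it is not a calibrated likelihood.

Selection models perturb F through an explicit generative mixture.  With
probability y(r) = exp(-r·tau), tau = log(4·Ne·s)/s, a selected
population's standardized frequency at recombination distance r is the
(unit-variance) state of the swept haplotype rather than its neutral
value.  This yields, for selected populations i, j:

    C_ii = (1-y)·F_ii + y
    C_ij = (1-y)^2·F_ij + y^2·share(r)     (sharing pairs)
    C_ij = (1-y)^2·F_ij                    (non-sharing pairs)
    C_iu = (1-y)·F_iu                      (u unselected)

`share(r)` encodes the mode: 1 for migration once the migrant allele is
established (an establishment lag max(0, log(1/(2·Ne·m)))/s applies when
2·Ne·m < 1, making very low migration rates distinguishable in
principle); exp(-2·r·t_st)/(1 + 4·Ne·g·r) for standing variation, the
probability that both lineages stayed on the shared background through
t_st generations of recombination, attenuated by coalescence on a
standing background at frequency g; and 0 for independent mutation.  The
two mixed models apply the sharing term only within a designated
same-lineage subgroup and treat the remaining selected population as an
independent origin.  Being the second moments of a well-defined mixture,
these matrices are positive semi-definite for every grid point and reduce
exactly to F as y → 0; the standing model reduces to the independent
model as t_st → infinity.  An earlier additive-inflation form that held
between-pair covariances at F under the independent model was rejected:
it produces indefinite matrices once within-pair correlation approaches
one while covariances to unselected populations stay neutral.

The fit is a grid search over models × parameters × 50 evenly spaced
proposed sites spanning the analysis region.  Default grids: s in
{1e-4, 1e-3, 1e-2, 1e-1}; t_st in {5, 10, 25, 50, 100, 500, 1000}
generations (the minimum of 5 makes the degenerate independent-model
estimate representable); g in {1/(2Ne), 1e-3, 1e-2, 1e-1}; m in
{1e-5, 1e-4, 1e-3, 1e-2}.  The independent model carries the
standing-time parameter; it is inert there, so its estimate sits at the
grid minimum with zero variance — the package reproduces this degeneracy
rather than hiding it, since it is what a grid MCLE genuinely does with
an unidentified parameter.  Exact likelihood ties break toward the model
with fewer live parameters.  Genes longer than 400 kb are skipped with a
record.

Numerics: the per-gene search evaluates the covariance on quantile-binned
SNP-to-proposed-site distances (48 bins by default) and scores parameter
combinations through per-bin scatter matrices, reducing the work per gene
from ~10^6 small Cholesky factorizations to a few hundred small
inversions.  48 bins resolves the standing-variation decay that
discriminates standing from migration; the coarser 24-bin grid measurably
blurred it.  `r_bins=None` recovers the exact per-SNP evaluation, and the
public `composite_loglik` is always exact; a brute-force multivariate-
normal oracle pins both to 1e-8 in the tests.  Selected sites are
classified against the annotation with precedence CDS > UTR > intron
inside the gene, and strand-aware upstream/downstream labels in the
flanks.  Reported percentages round half away from zero.

## Candidate intersections and downstream tests

A gene is *cave-adaptive* for a cave/surface pair (same lineage) when at
least one 5-kb window overlapping its full span (introns included) is
hard or soft in the cave population and every non-skipped window over the
span in the surface population is neutral or linked; linked calls are
never evidence of a sweep, and skipped windows are evidence-neutral (the
source classifications do not say how skipped windows were treated; the
choice is recorded here).  The *overlapping sweeps* set requires the
condition simultaneously for every cave against every surface, and is
therefore contained in each pairwise set.

Enrichments and comparisons use standard machinery: a one-sided
permutation test for QTL overlap that redraws equal-size gene sets
without replacement (5000 permutations; add-one p; Z reported missing
when the null is degenerate), Fisher's exact test (two-sided) on 2×2
count tables, Welch's unequal-variance t-test (candidate minus genome
sign convention) for transcript/CDS length, exon and isoform counts,
Kruskal-Wallis with midrank ties for sweep ages across phenotype
categories, and a one-sided exact rank-sum test for the cave-vs-surface
comparison of genome fractions under selection.  The convergent TFBS-loss
filter reports a (gene, flank, motif) triple when motif presence is at
least 80% in every surface population and strictly below 20% in every
cave population; the boundary semantics are exact and the filter is
monotone in its inputs.  Phenotype categories attach to genes by
case-insensitive substring matches of category keywords against GO term
names; multi-assignment is allowed.

## The synthetic-data generator

The study this package mirrors is observational, so no generative model
of the real data exists; the generator is a stand-in engineered to
produce the structure the inference keys on, with exact truth labels.

Neutral panels draw an ancestral frequency per SNP uniformly on
[0.05, 0.95] and evolve it down the two-lineage tree.  Drift per branch
is, by default, a single Gaussian step with variance x(1-x)·t/(2Ne)
truncated to [0, 1] (exact generation-by-generation binomial sampling is
available behind `exact_wf=True`); shared internal branches create the
within-lineage covariance the coancestry methods assume.  Haplotypes are
independent Bernoulli draws given the population frequency, so the
neutral background has no linkage — which makes the random-SNP
permutation null exactly calibrated on synthetic panels, a property real
data only approximates.

Sweeps are implanted by deterministic frequency surgery, not forward
simulation, so mode and hitchhiking decay are controlled exactly: the
beneficial allele is set to 0.99 at the selected site in each selected
population (0.01 from fixation so the site stays polymorphic through MAF
filters), and each flanking SNP in the region is replaced by the sweeping
haplotype's allele state with probability y(r) = exp(-r·tau).  Origins
encode the mode — per-population draws (independent), one haplotype drawn
at the source population's pre-sweep frequencies (migration), or one
shared haplotype whose state survives per population with probability
exp(-r·t_standing), falling back to an own draw (standing).  The
generator's second moments therefore match the inference model's mixture
covariance by construction; parameter recovery tests how well the grid
search inverts data generated under its own assumptions, plus drift
noise, *not* robustness to demographic misspecification, linked neutral
diversity, or sampling noise in called genotypes.

Default demography for the simulated experiments: diploid Ne 10,000 on
all branches, 500 generations root→lineage and 200 generations
lineage→population, one surface plus one/two caves per lineage (three
caves and four surface-cave replicate pairs mirror the published design
when extended to `caves_per_lineage=(3, 4)`), 10 diploid samples per
population.  These sizes put the drift scale (t/2Ne ≈ 0.01-0.025) in the
range where coancestry structure is visible at desk scale.

Recovery experiments use fixed conditions: s = 0.1, t_standing = 500
generations, standing frequency 1e-3; convergence-mode regions are
300 kb with a 100-kb candidate gene and 5 SNPs/kb, so the span's edge
reaches r ≈ 7e-4 Morgans where the standing survival probability
exp(-2·r·t_st) falls to ≈0.5 — the decay that separates standing
variation from migration needs that much room to express itself;
eigen-scan regions are 200 kb with 400 SNPs, scanned against a
3000-window neutral genome.  Locus-reuse truth is composed as two
lineage-internal shared-haplotype sweeps with independent origins
between lineages, which is what the term means operationally.

Emitted fixtures cover every downstream format: VCF 4.2 with genotypes
drawn binomially from population frequencies, GFF3 gene models tiled 10
kb every 50 kb (5'UTR 500 / CDS 3000 / intron 2000 / CDS 4000 / 3'UTR
500), three QTL intervals covering ~25% of the chromosome (a
non-degenerate permutation null), a truth-derived sweep-call table
(windows with a replaced SNP labelled hard when y at the window center
exceeds 0.9, else soft; adjacent windows linked), motif presence tables
with implanted convergent losses, GO annotations from a small vocabulary,
and the scenario-truth TSV.  All outputs are byte-reproducible from the
seed.

## Problem sizes and determinism

The shipped experiments are sized for a single CPU: 50 regions per mode
for both recovery suites, a 150,000-SNP neutral panel (3000 windows) for
calibration, and 10,000 permutations for every empirical null.  Every
stochastic stage derives a stage-named child seed from one master seed
(`SeedSequence([master, crc32(stage)])`), so stages are independently
reproducible and two runs with the same configuration are identical.

## Known limitations

- The generator's frequency surgery has no linked neutral coalescent
  structure; diversity statistics inside sweeps are reduced through
  haplotype replacement only.
- Composite likelihoods are treated as model scores; no confidence sets
  are attached to the MCLEs, and the migration rate is effectively
  unidentified above 2·Ne·m ≈ 1 (its MCLE is then grid-order dependent).
- The coancestry F estimated from a few thousand synthetic neutral sites
  carries sampling error that the model treats as exact.
- GO keyword matching is a substring heuristic; it stands in for curated
  keyword lists that are not distributed with the package.
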