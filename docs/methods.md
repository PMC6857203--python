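# Methods

`divergesim` studies the divergence history of a pair of closely related
populations (labelled K and W throughout, after the two shorebird lineages
that motivate the defaults) from whole-genome polymorphism data. It has two
halves: a coalescent ABC engine for demographic inference, and a genome
divergence scan with GO enrichment. This note documents the models, the
estimators, the numerical choices, and what the synthetic data can and
cannot show.

## Demographic models

Eight models describe the divergence, all sharing a single ancestral
population of diploid size `Ne_A` that splits at time `T` (years). Four
gene-flow scenarios — isolation (`ISO`), isolation-with-migration (`IM`),
early migration only in `[T1, T)` (`EM`), and secondary contact only in
`[0, T1)` (`SC`) — are crossed with two effective-size regimes: constant
sizes `Ne_K`, `Ne_W` (group A) or sizes that change at `T1` from the old
values `Ne_K`, `Ne_W` to present-day values `N0_K`, `N0_W` by exponential
interpolation (group B). Migration strength is parameterised as `2NM`, the
number of immigrant individuals entering the recipient population per
generation, so the backward per-lineage migration rate in recipient *i* is
`M / (2 N_i(t))` — time-varying inside growth epochs. Group-B growth is
endpoint-parameterised; the per-generation growth coefficient
`ln(Ne_i / N0_i) / (T1 / g)` is derived, never sampled, which avoids
over-determining the epoch.

Internal units follow the ms convention: time in `4 N_ref` generations,
sizes relative to a fixed reference `N_ref = 1e6` diploids,
`theta = 4 N_ref mu L`. All user-facing parameters are natural units
(years, individuals) converted via the generation time `g`. Defaults:
`mu = 0.8e-8` per site per generation and `g = 2.5` years — both are
configuration values, not constants, because the source estimates are
mutually inconsistent (an alternative published rate of `8.11e-8` per bp
per *year* implies a ~25-fold larger per-generation rate).

### Simulation engine

The structured coalescent is sampled exactly: within each epoch, competing
exponential waiting times for within-population coalescence (with
closed-form time rescaling in exponential-growth epochs) and per-lineage
migration; at `T` all lineages merge into the ancestral population. The
hot path is numba-compiled and uses an inline xorshift128+ generator
(seeded per locus through splitmix64 from counter-derived child seeds, so
locus *j* of simulation *i* is reproducible independently of the others)
and a PTRS Poisson sampler for mutation counts.

Mutations follow the infinite-sites model: per-branch counts are
`Poisson(branch length x theta)`; when haplotype matrices are materialised,
positions are drawn without replacement on the `L` bp grid (a finite-`L`
approximation of infinite sites). For reference-table construction the
matrices are never built: every tree node carries its descendant tips as a
64-bit mask (capping samples at 64 haplotypes; the defaults use 20 + 20),
and all per-locus statistics are computed from branch-level mutation
counts and mask popcounts, making the per-simulation cost independent of
`theta`. Haplotypes `(2j, 2j+1)` form diploid individual `j`; heterozygote
and dosage summaries come from bit-pair tricks on the same masks, which is
why per-population sample sizes must be even.

There is no intra-locus recombination; loci are independent (the intended
data are 10-kb loci spaced > 500 kb apart). The engine is cross-checked in
the test suite against closed forms (E[TMRCA], Watterson's E[S], the
neutral site-frequency spectrum) and distributionally against msprime at
identical scaled parameters.

## Summary statistics

Per locus: nucleotide diversity per population (allele-count form of mean
pairwise difference, per site), Tajima's D per population and pooled
(undefined below 3 segregating sites), Weir–Cockerham (1984) F_ST on
diploid dosages aggregated as a ratio of sums with negative estimates
retained, d_XY (Nei's between-population mean difference per site), the
count of fixed differences, and mean dosage r² over site pairs. With
missing data, allele counts are sitewise-complete; sites with fewer than
two called genotypes in either population drop out of F_ST.

Mean r² is the one estimator with a cost quadratic in the number of sites,
so the engine computes it exactly only when a locus has at most 300 site
pairs and otherwise averages 100 uniformly sampled pairs (unbiased). The
same rule is applied to ABC-facing *observed* summaries
(`mean_r2(..., exact_cap=300)`): estimator consistency between the observed
and simulated sides matters — using the exact estimator on the observed
side inflates the across-locus variance of r² in reference rows relative
to the observation and measurably degrades model choice.

The ABC summary vector is the across-locus mean and unbiased variance of
(pi_K, pi_W, D_K, D_W, F_ST, d_XY, r²) in that order — 14 entries. Loci
with undefined values are excluded per statistic and counted.

## ABC

Reference tables are prior-predictive samples: one parameter draw, one
30-locus dataset, one summary vector per row. Default priors: sizes
log-uniform(1e4, 1e7); `T` uniform(0.2, 2.0) Ma; `T1` normal(0.06 Ma,
0.02 Ma) truncated to (1e3 years, T); `2NM` uniform(0, 500) per direction.
A simulation filter mirrors the locus-acceptance region of the intended
observed data: rows with mean F_ST > 0.159 or mean pooled D outside [0, 1]
are discarded (configurable, and optional — see "known limitations").

Distances are Euclidean on columns scaled by their raw median absolute
deviation (constant columns dropped with a warning); the accepted set is
the `ceil(tolerance x rows)` nearest rows with ties broken by row index,
floored at 50 rows for model choice.

*Model choice* reports both the rejection posterior (acceptance
proportions) and a multinomial logistic regression of model label on
scaled summaries over the accepted rows, weighted by the Epanechnikov
kernel `w = 1 - (d/d_max)^2` and evaluated at the observation (an
essentially unpenalised sklearn fit, C = 1e4). Models absent from the
accepted set get probability zero with a warning. A two-stage protocol
(choose within each size-regime group, then compare the group winners) is
provided alongside the pooled eight-way comparison. Bayes factors are
posterior-probability ratios under equal model priors.

*Parameter estimation* uses homoscedastic neural-net regression
adjustment: an ensemble (default 50, reduced-scale runs use 10) of
single-hidden-layer networks (5 tanh units, linear output, weight decay
drawn per network from {1e-4, 1e-3, 1e-2}, L-BFGS training on
standardised inputs and targets, Epanechnikov sample weights) regresses
log-parameters on scaled summaries over the accepted rows; each accepted
draw is corrected by `theta* = m(s_obs) + (theta - m(s))` with the
ensemble-mean prediction `m`. Point estimates are weighted medians, means
and a mode from a weighted Gaussian KDE (Silverman bandwidth) on the log
scale; intervals are weighted 2.5%/97.5% quantiles (simple quantiles, not
HPD). Degenerate cases (a single accepted row, all-zero distances, or a
constant accepted design) fall back to the unadjusted draws.

The adjustment is validated against a conjugate linear-Gaussian oracle;
leave-one-out cross-validation of model choice gives a confusion matrix.
When comparing models, tables should carry (approximately) equal retained
row counts: the rejection posterior is proportional to row counts, so
unequal retention (isolation models retain ~1.5% of prior draws against
~18% for migration models) silently biases the implicit model prior.

## Genome scan

Variant input is a VCF reduced to biallelic SNPs (multi-allelic records
and indels dropped; half-called genotypes treated as missing). The
prefilter keeps sites with missing fraction <= 0.10 and minor-allele
frequency strictly > 0.05, then enforces at most 3 SNPs in any 10-bp
window per scaffold by greedy left-to-right removal of the rightmost
excess site (the tie-break is a convention; it is recorded here because no
source fixes it).

Windows are non-overlapping 50-kb tiles starting at the first scaffold
base; windows spanning under 25 kb of scaffold (terminal truncation, not
callable length) are excluded. Per-gene statistics are computed on merged
CDS intervals only. W-chromosome scaffolds are excluded; scaffolds absent
from the scaffold map are classed unassigned and their genes flagged out
of the percentile universe. Percentile cutoffs use the type-7
linear-interpolation quantile within each chromosome stratum (autosomes
and Z separately); outliers lie strictly beyond the cutoff, and for
Tajima's D the high/low cutoffs are the 95th percentile of positive and
5th percentile of negative values per species. Strata with too few defined
(or same-signed) values are skipped with a warning rather than failing the
panel. Note that window d_XY shares the filtered SNP set of every other
statistic (invariant sites are assumed identical), a uniform downward bias
across windows.

ABC loci are extracted from the variant table as random non-overlapping
10-kb segments on scaffolds with callable fraction > 0.8, start-to-start
distance > 500 kb, dropping loci where any individual misses > 40% of
sites or average missingness exceeds 30%, then applying the locus filter
(F_ST <= 0.159, pooled D in [0, 1]); all exclusion tallies are reported.

## Enrichment

For an outlier gene set, each GO category's expected membership is the
mean over 1,000 equally sized random draws from the gene universe without
replacement; significance is a Z-score against the resampling spread with
a two-sided normal p-value and Benjamini–Hochberg correction across the
categories of each domain (biological process and cellular component
separately; adjusted p < 0.05). Categories with zero resampling spread are
flagged untestable (unless the observation equals the constant expectation,
a well-defined Z = 0); categories with expected count < 1 and at most one
observed gene are flagged as unsupported singletons after correction.
Annotation handling: categories under 50 members merge into one `small`
category per domain, genes without domain annotation form that domain's
`uncharacterized` category, and no GO-graph propagation is performed.
The normal approximation is adequate for categories whose expected counts
are a few or more; the empirical-tail alternative was considered and left
out because the filtered categories (>= 50 members) stay comfortably in
the normal regime at the default universe sizes.

## Synthetic data

`make_pseudo_observed` draws multi-locus diploid datasets under any model
(defaults: 30 loci of 10 kb, 20 + 20 haplotypes) with optional uniform
per-genotype missingness, written as VCF + popmap + truth ledger.
`make_toy_genome` builds a six-scaffold genome (4 autosomal scaffolds +
one Z + one deliberately unmapped scaffold, 2 Mb each, ~200 windows) whose
background windows are simulated under a symmetric two-population model
with migration calibrated to mean F_ST 0.046 and background diversity
2.6e-3, and whose two islands (1% of windows) use migration calibrated to
F_ST 0.6. Island divergence is therefore mechanistic — the island windows
have their own low-migration genealogies — so pi, d_XY and D co-vary as
they would in real reduced-gene-flow regions. Genes are tiled at 20-kb
spacing with three CDS exons; a planted GO category is assigned to island
genes at odds ratio 20 against a baseline membership of 60/500 genes, and
~10% of genes carry no annotation. Migration calibration is a
common-random-numbers bisection on log(2NM) against the mean F_ST of
4,000 simulated loci, run to full depth (residual error ~0.006 on the
F_ST scale; the early-stopping variant is biased by the stopping rule).

What the toy data do *not* emulate: linkage within and between windows
(each window is an independent genealogy), sequencing error and reference
bias, unequal sample depths, selection (islands arise from restricted
gene flow only), and GO-graph structure. Passing the planted-truth tests
therefore shows the pipeline recovers localized differentiation and
over-representation signals of realistic magnitude, not that it is robust
to those artefacts.

## Problem sizes and seeds

Acceptance-style runs use the geometry of the intended study (30 loci of
10 kb, 20 + 20 haplotypes) with reference tables of 5,000 retained rows
per model for model choice and 20,000 rows for parameter estimation
(ensemble of 10 networks at this scale); the self-consistency
cross-validation in the test suite uses 2,000 retained rows per model.
These sizes are the package's reduced-scale defaults; posteriors sharpen
with more simulations, and the full-scale analogues are 1e6 simulations
per model and 5e6 for the chosen model with 50 networks. All randomness
descends from a single root seed through `numpy.random.SeedSequence`
(per-locus streams by counter, so extending a dataset leaves earlier loci
unchanged); reruns with the same configuration are bit-identical.

## Known limitations

* The simulation filter and the published parameter medians are mutually
  inconsistent under `mu = 0.8e-8`/generation: data simulated at those
  medians have mean pooled Tajima's D near -0.6 and would be discarded by
  the filter, so parameter-recovery runs at those medians use unfiltered
  reference tables (the filter remains the default for model choice).
* With `T1` near 0.06 Ma and size priors reaching 1e7, early-migration and
  isolation-with-migration models nest the secondary-contact signature;
  at 30 loci the secondary-contact scenario is recovered in only ~55-62%
  of held-out cross-validation cases (isolation: ~85%).
* The ratio of the two descendant effective sizes is weakly identified at
  these conditions: strong recent migration mixes the populations, leaving
  only the older epoch's small coalescence share (a 10-15% effect on mean
  pi) to separate the sizes, which 30 loci cannot resolve.
* Samples are capped at 64 haplotypes (bit-mask representation) and
  per-population counts must be even (fixed diploid pairing).
* Tajima's D with missing data uses sitewise-complete counts with
  nominal-n normalisation constants, a standard but approximate choice.
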