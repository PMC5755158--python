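# Methods

`herdqg` re-implements, as a tested and reusable pipeline, a longitudinal
analysis of fecal-microbiota composition and diversity in a pedigreed pig
herd: compositional screening, enterotype discovery, alpha-diversity
phenotyping, and pedigree-based estimation of heritabilities and genetic
correlations. This note records the models, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## OTU-table processing

The pipeline starts from a classic tab-separated OTU count table (samples x
OTUs with a semicolon-delimited lineage column). Sparse OTUs are removed by
a grand-total threshold (default 1200, inclusive at the boundary), and
samples are rarefied to a fixed depth (default 10,000 reads) by multivariate
hypergeometric subsampling — drawing without replacement, so samples below
the target depth are dropped rather than up-sampled. Good's coverage
(1 − singletons/total) summarizes sampling completeness per sample.

Counts are aggregated to a named taxonomic rank by summing within rank
labels (unmapped OTUs pool into an `unclassified` bucket; totals are
conserved). Compositional transforms: relative abundance (rows sum to 1)
and a log-centered transform — zeros replaced by half the smallest nonzero
value in the matrix (configurable to a fixed pseudocount), natural log, each
row centered to mean zero. Natural log is used throughout the package so
the transform scale matches the Shannon index in nats. PCA operates on the
covariance (not correlation) of the log-centered values, since the
processing centers but never scales; per-taxon contributions to a component
are squared-loading shares in percent. The Kruskal–Wallis screen applies
scipy's tie-corrected H per taxon with Bonferroni adjustment over the number
of taxa tested in that screen; because rank tests are invariant to monotone
transforms, it makes no difference whether the input is relative or
log-transformed abundance.

## Enterotyping

Samples are compared by the square root of the Jensen–Shannon divergence
between genus-level relative-abundance profiles (natural log; zeros replaced
by a 1e-10 pseudocount and rows renormalized). The square root is used
because it is a metric — verified by a triangle-inequality property test —
and distances are bounded by sqrt(ln 2).

Clustering is partitioning around medoids. Tiny instances (up to ~3000
candidate medoid sets) are solved exactly by enumeration; larger ones use
the deterministic BUILD+SWAP heuristic — greedy medoid seeding followed by
steepest-descent single swaps, ties broken on the lowest sample index. No
random restarts are used, so results are seed-free. Steepest-descent
k-medoids can stall in a local minimum on adversarial tiny instances (we
observed one five-point example), which is why the exact path exists; at
the sample sizes of a real time point the heuristic recovers planted
partitions reliably in our simulations.

The number of clusters is chosen by maximizing the Calinski–Harabasz index
over k = 2..10 by default. Because CH is a sum-of-squares ratio, it needs
coordinates: we embed the distance matrix by classical principal-coordinates
analysis and drop negative-eigenvalue axes, the standard treatment for
non-Euclidean dissimilarities. Mean silhouette width is reported alongside
but does not drive the choice. A flat CH curve — maximum within 25% of the
median across k — raises a stability warning instead of a confident cluster
number; that margin cleanly separates planted-structure curves (ratios of
2 and more) from structureless Dirichlet noise (within ~10%) in our
simulations.

Genera separating two enterotypes are ranked by an LDA effect size in the
LEfSe style, restricted to the two-class case the analysis needs:
abundances are rescaled per sample to one million; genera failing a
Kruskal–Wallis test at alpha = 0.05 are excluded; for the rest, the effect
size is log10 of the absolute average of the raw class-mean difference and
the difference of the genus's component along the unit-norm Fisher
discriminant axis (pooled covariance with a small ridge), averaged over 30
bootstrap resamples by default (`n_boot=0` gives a deterministic single
fit for testing). The sign marks the enriched class; significance requires
|score| strictly greater than 2.

Longitudinal structure is summarized by per-animal transition contingency
tables between consecutive time points (row percentages sum to 100) and by
a Pearson chi-square of the sire-family x enterotype table.

## Diversity phenotypes

Shannon diversity is H = −Σ p_i ln p_i in nats over an individual sample's
rarefied OTU proportions; OTU richness is the count of OTUs present at the
fixed depth. Both are computed at the OTU level, not after taxonomic
aggregation. Post-weaning measurements are pre-adjusted for contemporary
group by subtracting group means and restoring the grand mean (idempotent;
singleton groups map exactly to the grand mean); weaning measurements
precede contemporary grouping and are left unadjusted. Richness receives
the same adjustment as the Shannon index by default, with a flag to disable.
Enterotype contrasts in diversity use Welch's unequal-variance t-test within
sex, the conservative choice given markedly different spreads between
community types.

## Quantitative genetics

The additive relationship matrix A is built by the tabular recursion over a
parent-first ordering (`a_ii = 1 + a_{sd}/2`, `a_ij = (a_{j,s} + a_{j,d})/2`),
validated against gene-dropping Monte-Carlo IBD estimates and textbook
forced values. Dense storage is used throughout; pedigrees to a few
thousand animals fit comfortably, and sparse inverse-A machinery is an
extension point rather than a need at this scale.

Variance components are estimated by average-information REML: Newton steps
on the AI matrix with the exact gradient, backtracked if the restricted
likelihood would fall, and replaced by an expectation-maximization update —
which cannot decrease the likelihood — whenever the AI step leaves the
parameter space. Variance estimates are floored at 1e-8 times the
phenotypic variance; convergence requires both relative parameter change
and likelihood change below 1e-8 (maximum 200 iterations; non-convergence
is flagged and the last iterate returned). Standard errors come from the
inverse AI matrix, and heritability SEs by the delta method.

Two linear-algebra back ends sit behind one interface: a dense path that
factorizes V = Σ θ_k K_k directly (required when the animal term carries
the dense A structure over records), and a Woodbury identity path for
models whose random terms are all low-rank identity-covariance factors
(sire, family-by-age, litter, pen), costing O(n q²) per iteration. The
back end is chosen automatically from the total random-effect rank relative
to the record count; both give identical estimates on shared problems
(tested).

The standard model ladder mirrors longitudinal practice: a fixed-effect
screen with sex, age x family, birth site, and dam line; a litter
(common-environment) model at single ages; and animal models of increasing
environmental detail — additive genetic only, plus litter, plus pen — the
pen term applying only post-weaning. Heritability is the animal variance
over the sum of all fitted components including litter and pen; that
denominator is a documented, configurable choice since a total-variance
convention must be fixed somewhere. Wald F statistics for fixed effects are
sequential (type-I) at the converged V, matching stepwise model building.

Bivariate REML stacks the two traits' records, estimates 2x2 covariance
matrices per random structure (animal via A, environmental terms and
residual via identity on animals), retains records missing one trait, and
reports genetic and phenotypic correlations with delta-method SEs. A
converged covariance outside the PSD cone is bent to 0.999 of the boundary
and flagged rather than silently reported.

Model comparison uses the likelihood-ratio test with the boundary-corrected
half-and-half mixture chi2_0 : chi2_1 reference for one extra variance
component; the naive chi-square p-value is emitted alongside. A statistic
of exactly zero is assigned the mixture p of 0.5 by convention.

Longitudinal family profiles fit sex and birth site as fixed with a random
age x family interaction, predict its shrunken (BLUP) effects, center them
within age, and correlate per-family profiles between ages with
pairwise-complete Pearson correlations. The interaction is random by
default (a fixed-effect mode exists) because shrinkage stabilizes the
28-family profiles.

## The synthetic herd

No raw data accompany the study design this package targets, so a
generator provides every input with known truth. Its defaults encode the
emulated design: 28 purebred sires, 26 dams per sire (~728 litters, one
litter per dam), one to two sampled progeny per litter, single-sex
single-family pens of up to 20, six contemporary groups, three birth sites,
two dam lines, three sampling ages (weaning ~18.6 d, week 15 ~118 d,
off-test ~196 d), and OTU tables at 10,000 reads per sample. Sexes
alternate within litter to balance the design. All randomness derives from
one root seed through named substreams (pedigree/design/traits/otu), so any
stage regenerates independently and byte-identically.

Traits are drawn under the animal model: breeding values by the gene-flow
recursion u_i = (u_s + u_d)/2 + Mendelian term with variance
[1 − (a_ss + a_dd)/4]·G0 — the exact lower-triangular factorization of A —
and litter, pen, and residual effects iid at their nominal variances.
Default trait architecture: weaning diversity nearly non-heritable
(h² = 0.04) with a large litter share, post-weaning diversity moderately
heritable (0.17–0.19) with litter 0.10 and pen 0.05, production traits near
h² = 0.3. The default genetic correlation matrix is built from a two-factor
loading structure (a production axis and a post-weaning diversity axis), so
it is positive semi-definite by construction while placing the week-15
diversity vs back-fat correlation near −0.5.

OTU tables come from a two-component Dirichlet-multinomial mixture per time
point: an Escherichia/Enterococcus-led versus a Prevotella-led community at
weaning, Clostridium/Turicibacter versus Lactobacillus/Streptococcus/
Prevotella afterwards, with concentration 60 and genus means split into
five OTUs per genus. Enterotype propensity carries a per-family logit
shift (SD 0.8) so family and enterotype are associated; each animal's
latent diversity breeding value shifts its community toward or away from
evenness, giving the *measured* Shannon index a heritable component without
circularity in the trait simulation.

What the generator does not emulate: sequencing error and read-level
processing, batch or run effects, diet and medication interventions,
selection across generations, and taxa whose presence/absence changes with
age. Passing tests therefore demonstrate correctness of the estimators and
the recoverability of planted structure under a clean design — not
robustness to the messiness of real amplicon data.

## Problem sizes and runtime

Validation and the acceptance script run at deliberately reduced scale so
the whole suite completes on one CPU in minutes: recovery grids use herds
of ~800 animals with 3–4 replicates per cell, likelihood-ratio calibration
uses 200 replicates of ~240-animal herds, power checks 60 replicates of
~580-animal herds with a planted litter share of 0.5 (a deliberately large
common-environment signal), and the acceptance script runs microbiome
stages at ~600 samples per time point with univariate genetics at the full
emulated design (~1,456 animals) and the bivariate fit at ~600 animals.
Monte-Carlo tolerances are always stated as multiples of the replicate
standard error, floored by the analytic SE so small replicate counts cannot
understate the noise.

## Known limitations

- PAM is exact steepest-descent but, like all local k-medoids, carries no
  global-optimality guarantee beyond the small instances tested.
- The LDA effect size is a faithful two-class re-implementation of the
  LEfSe idea, not a bug-for-bug port; absolute scores can differ from other
  implementations even though rankings agree.
- Multi-trait REML is limited to trait pairs; three-or-more-trait systems
  must be analyzed pairwise.
- Dense linear algebra bounds practical pedigrees to a few thousand
  animals per fit.
- Repeated records per animal within one trait are not modeled (each
  animal contributes one record per trait per fit), matching the
  one-sample-per-age design.
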