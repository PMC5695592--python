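# Methods

`morphopop` reimplements, as a reusable library, the joint morphometric and
microsatellite analysis used in plant-domestication studies that compare
wild, managed and cultivated populations.  This note documents the models,
the estimators, the synthetic-data generator, and the numerical and design
choices that were genuinely open.

## Morphometric pipeline

**Standardization.** Each character Y is z-scored, Y0 = (Y − a)/b with a
the mean and b the sample standard deviation (ddof = 1), because lengths
(cm), counts and dimensionless ratios are mixed.  Characters with b = 0
are flagged on the returned parameter object and excluded, never silently
dropped.  Stored parameters can be re-applied to new data and reproduce
the training transform bit-identically.

**Sturges categorization.** A character scored on n plants is cut into
k = ⌈1 + log₂ n⌉ equal-width classes spanning the pooled [min, max].  n is
pooled across *all* populations so that one shared set of bin edges makes
state frequencies comparable between populations — required for the PDI.
Interior bin edges belong to the lower bin; the maximum goes to class k.
Bin edges are stored with the categorical matrix for reproducibility.

**MDI.** Per character the Simpson-type heterogeneity 1 − Σᵢ pᵢ², where pᵢ
is the proportion of plants in the group showing state i (missing cells
are excluded from the denominators).  The group MDI is the *unweighted
mean over characters*: the single-character formula is standard, and the
averaging rule is this package's choice of how to "summarize in a single
metric" — it weights every character equally regardless of its class
count.  MDI ∈ [0, 1 − 1/s] and is maximized by uniform state frequencies.

**PDI.** Nei's (1972) standard genetic distance applied to character-state
frequency profiles, treating each character as a locus and each Sturges
class as an allele: D = −ln(J_xy / √(J_x·J_y)) with the J terms summed
over characters before the ratio.  Groups sharing no state at any
character get an infinite distance, flagged rather than capped.  The Nei
(1978) small-sample variant is available via `unbiased=True`; the classic
1972 form is the default.

**Rank ANOVA.** Kruskal–Wallis H with midrank tie correction (via
`scipy.stats.kruskal`), chi-square p on (groups − 1) df.  Pairwise
Dunn-type z comparisons on mean ranks with Bonferroni adjustment are
summarized as compact-letter-display codes; groups that share no letter
are significantly different at the chosen alpha.

**Discriminant analysis.** Canonical LDA by the generalized eigenproblem
S_b v = λ S_w v of between- vs within-class scatter.  Reported are
per-axis fractions λⱼ/Σλ, variable loadings, Wilks' Λ = Π 1/(1 + λⱼ) with
the Bartlett chi-square approximation (−(n − 1 − (p + g)/2)·ln Λ on
p(g − 1) df), and a confusion matrix from leave-one-out reclassification
by nearest class centroid in discriminant space (the left-out plant is
removed from its own centroid; axes are kept fixed, which is the usual
fast approximation).  A singular within-class scatter is ridge-regularized
with ε = 10⁻⁸·tr(S_w)/p, logged.

**Character selection.** Which characters enter the categorical matrix is
always an explicit argument.  A helper reproduces the usual filter
(Kruskal–Wallis p ≤ 0.05 plus largest |loading| on DF1/DF2) but is never
applied implicitly.

## Population genetics

**Diversity.** Per locus: NA = observed alleles, NE = 1/Σp², H_O =
heterozygote fraction among typed plants, H_E = 1 − Σp², UH_E =
2N/(2N − 1)·H_E.  Population values are means over loci with standard
errors over loci.  Alleles are exact fragment sizes in bp; no binning.

**Null-allele EM.** One null allele per locus under Hardy–Weinberg:
visible heterozygotes are (i, j), a visible homozygote i is either i/i or
i/null, and a blank genotype is null/null.  The E-step apportions visible
homozygotes with weight p_i/(p_i + 2r) and assigns blanks to the null
class; the M-step re-estimates frequencies by expected gene counting.
Iteration stops at |Δr| < 10⁻⁸ or 10 000 iterations; non-convergence is
flagged and the last iterate returned.  The observed-data log-likelihood
is non-decreasing (tested).  Attributing all blanks to null homozygotes
slightly overestimates r when genuine amplification failures occur; this
is the standard operational assumption.

**F-statistics.** Weir–Cockerham variance components a (among
populations), b (among individuals within), c (within individuals),
computed per allele per locus; the multi-locus estimate is the ratio of
sums.  The 95% CI is a percentile bootstrap over loci (default 10 000
replicates, seeded).  Per-population F_IS uses the within-population (b, c)
components with r = 1 population: f = 1 − Σc/Σ(b + c); this reproduces the
exact bounds f = 1 (all homozygotes) and f = −1 (all heterozygotes at
p = ½).

**ENA correction.** Null alleles inflate the uncorrected θ when their
frequency varies among populations (drift), because the apparent visible
frequencies then carry spurious between-population variance.  The
correction appends the EM-estimated null frequency as an extra allele per
locus × population and excludes that allele from the numerator and
denominator sums.  Concretely the estimator is evaluated on the EM
complete-data reconstruction: visible frequencies summing to 1 − r plus
the null at r; blanks counted as null homozygotes (so n is all plants);
and observed heterozygosities augmented by the expected visible/null
heterozygotes the EM attributes to apparent homozygotes.  A naive variant
that rescales frequencies but keeps raw heterozygosities is structurally
downward-biased (≈ 0.75×) and was rejected.  Per-locus terms with
non-positive denominators are dropped from the multi-locus ratio.

**Distances.** Nei D as for the PDI but over loci, with an optional 1978
unbiased form.  Cavalli-Sforza & Edwards chord distance per locus
d_l = (2√2/π)·√(1 − Σᵢ√(xᵢyᵢ)), multi-locus DC = √(Σ d_l²/L); the INA
variant includes the two populations' estimated null alleles as an
additional shared allele inside the square-root sum.

**Hardy–Weinberg exact test.** Monte-Carlo version of the exact test:
the probability of the observed genotype array conditional on allele
counts (Levene's formula, computed in log space) is compared to arrays
obtained by randomly re-pairing the observed gene copies;
p = (1 + #{perm ≤ obs})/(1 + n_perm).  Monomorphic cells give p = 1.

**Demography.** Only the algebraic conversions are implemented:
Ne = Θ/(4μ) and Nm = Θ·M/4, with μ defaulting to 5 × 10⁻⁴ per generation
(a standard average microsatellite rate; configurable).  For the pipeline
report a moment estimate of Θ is taken from H_E under the stepwise
mutation model, H = 1 − 1/√(1 + 2Θ).  Coalescent likelihood estimation of
Θ and M is out of scope.

## Clustering and AMOVA

**UPGMA.** Hand-implemented average-linkage agglomeration with
cluster-size weighting, deterministic lexicographic tie-breaking, node
heights equal to half the merge distance (ultrametric by construction).
scipy's average linkage serves as an independent oracle in the tests,
not as the implementation.  Bootstrap supports resample loci (or
characters) with replacement and report the percentage of replicate trees
containing each original clade.

**Admixture model.** Gibbs sampler over cluster-origin indicators Z per
gene copy, cluster allele frequencies P (conjugate Dirichlet updates;
under the correlated-frequency model the prior is the F-model Dirichlet
around empirical overall frequencies with fixed strength F_prior = 0.05,
rather than per-cluster Metropolis updates of F_k — a deliberate
simplification), admixture proportions Q ~ Dirichlet(α + counts), and a
random-walk Metropolis update of α (uniform prior on (0, 10), step
SD 0.25).  Categorical morphology matrices run through the same sampler
as haploid loci with Sturges classes as alleles.  LnP(K) is the standard
estimate mean(L) − var(L)/2 of the per-sweep log-likelihood of the data
given (P, Q).  Desk-scale defaults (burn-in 5 000, 50 000 sweeps) are
deliberately far below publication-scale runs; all lengths are arguments.

**Evanno ΔK.** ΔK(K) = |L(K+1) − 2L(K) + L(K−1)| / SD(LnP(K)) over runs;
undefined where the run SD is zero (flagged NaN, not infinite).  The
argmax of mean LnP(K) is reported alongside.  ΔK requires several runs
per K to estimate the SD stably; the tests use 5–10 runs per K, matching
common practice of ~10 runs.

**Label alignment.** Cluster columns of each run are permuted to best
match the first run, maximizing summed column Pearson correlation —
exhaustive over permutations for K ≤ 8, greedy above.

**AMOVA.** Computed at the gene-copy level per locus: units are the 2N
typed allele copies, distance is the squared allele-size difference (the
stepwise-mutation-model metric, making the Φ statistics R_ST-analogues).
Sums of squares decompose into among-groups / among-populations /
within-populations; variance components come from the standard
expected-mean-squares coefficients with unequal sample sizes, summed over
loci.  Percentages are computed against the *sum* of the components
(where a printed total disagrees by rounding, the sum governs).  Φ_ST =
(among components)/total, Φ_CT = among-groups/total.  Significance:
permutation of individuals among populations (Φ_ST) and of populations
among groups (Φ_CT), 1 000 permutations by default, seeded.  Negative
components are retained (they are moment estimates), not clipped.

## Synthetic-data generator

The generator emulates the sampling design of a 24-population,
three-species, three-management-class study: 10 microsatellite loci with
8 ancestral alleles spaced 2 bp apart (dinucleotide convention), 19–30
plants per population, and 23 vegetative characters.

* **Genotypes.** A two-level F-model: species-level pools diverge from a
  common ancestral pool with F_cluster, populations from their pool with
  per-population F (Dirichlet(p·(1 − F)/F), the Balding–Nichols form;
  F → 0 is handled as the limit).  With no clusters this is the plain
  one-level F-model, which the Weir–Cockerham estimator recovers
  (|mean θ̂ − F| < 0.05 across F ∈ {0.05, 0.15, 0.3}).
* **Null alleles** act per allele copy: visible/null heterozygotes are
  recorded as visible homozygotes, null/null as missing.  Two modes:
  exact per-population frequency (used for EM recovery tests) and
  `null_drift`, where the null joins the parent pool and drifts under the
  same F — the regime in which the uncorrected θ is inflated and the ENA
  correction earns its keep.  With constant null frequency across
  populations the uncorrected θ is essentially unbiased (verified
  numerically), so bias-reduction checks use the drift mode.
* **Clones.** With the configured probability an individual copies the
  *latent* genotype (including null states) of an earlier individual in
  its population, mimicking vegetative propagation in cultivated stands;
  the default design gives the domesticate a clonality of 0.5.
* **Traits.** Multivariate normal around species × management group
  means.  The default means and standard errors are of the magnitude
  reported for wild/managed/cultivated agave groups (general plant length
  ≈ 98–201 cm across groups); per-plant SD is taken as 6 × SE (group
  sizes of ~36), and covariances are diagonal — group trait correlations
  are not emulated.  Negative draws for strictly positive characters are
  truncated at 0.01.

What the generator does *not* emulate: linkage between loci, mutation
during sampling, genotyping error other than nulls, trait correlations,
phenotypic plasticity, and spatial structure.  Passing tests therefore
show the estimators are correct under their own generative assumptions,
not that field data meet those assumptions.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately modest sizes chosen
as the smallest that make the Monte-Carlo checks statistically stable:
20 replicates for recovery checks, 200 loci × 400 permutations for the
HWE calibration, 100 bootstrap replicates per tree, and K = 1..5 with
5–10 runs of a 400–500 burn-in / 1 000–1 500 sweep sampler for the ΔK
experiment.  EM tolerance 10⁻⁸; Dirichlet parameters are floored at 10⁻⁶
to avoid exact zeros; log-probabilities floor their arguments at 10⁻³⁰⁰.
All stochastic stages take explicit seeds; the pipeline derives per-stage
seeds from one master seed by hashing the stage name.

## Known limitations

* F_IS is the moment estimator; the Bayesian inbreeding-with-nulls model
  some studies use is out of scope, so F_IS in the presence of nulls is
  upward-biased.
* The admixture sampler holds the F-model prior strength fixed instead of
  sampling per-cluster F_k, and does not auto-detect non-convergence (the
  log-likelihood trace is exposed for inspection).
* ΔK is undefined at the end points K_min and K_max and is known to favor
  the top level of hierarchical structure; with three equidistant
  clusters it occasionally selects K = 2 on unlucky draws.
* AMOVA treats the two gene copies of an individual as independent units
  (no within-individual level), matching the three-row table layout it
  reproduces.
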