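# Methods

This note documents the models, estimators and design choices behind
firpopgen, and what the synthetic-data experiments do and do not establish.

## Data model

Genotypes are diploid allele-size calls (integers, base pairs) per
individual × locus. A call is atomic: both alleles present or both missing;
half-missing input is promoted to fully missing with a warning, because all
downstream estimators need per-locus diploid completeness. Taxon labels and
coordinates live in a sidecar CSV since GenePop has no group concept. Loci
known to misbehave (null alleles, shared repeat segments, indel-prone
loci) are removed by config-level exclusion lists, not re-detected.

## Diversity

Gene diversity is Nei's unbiased estimator Ĥ = n(1−Σp̂ᵢ²)/(n−1) per locus,
averaged arithmetically over loci with n ≥ 2 gene copies. Allelic richness
uses exact hypergeometric rarefaction (computed with rational arithmetic,
so it equals brute-force subsample enumeration to machine precision);
private allelic richness follows Kalinowski's estimator
P_g(j) = Σᵢ Q_g(i,j) Πₖ≠ⱼ(1−Q_g(i,k)). Default rarefaction sizes are 22
gene copies at the population level and 140 at the taxon level (copies
pooled across the taxon's populations); populations below the rarefaction
size are excluded and reported. Both sizes are configurable.

## Differentiation

F-statistics use the Weir–Cockerham (1984) moment estimator: per allele and
locus the components a (among populations), b (among individuals within
populations) and c (within individuals) are computed with sample-size
weighting and the observed heterozygosity term; the multilocus θ is the
ratio of sums. Negative estimates are retained (they are sampling noise
around zero), except in Slatkin's linearization F/(1−F), where negative F
is truncated to 0 and flagged, because a genetic *distance* cannot be
negative.

AMOVA operates on gene copies with the allele-identity distance (the
F_ST-like choice, matching the study design's F-statistics reporting; an
allele-size-squared distance would estimate R_ST instead, which is out of
scope). For 0/1 identity distances, the SSD of a set of m copies with
allele counts c_a collapses to (m² − Σc_a²)/(2m), which makes permutation
testing cheap. Variance components come from the standard nested ANOVA
expected mean squares with unequal-size coefficients; loci are analysed
separately (df and components summed), which is also how missing data are
absorbed — the exact df accounting of other programs under missing data is
implementation-defined, and we document ours rather than reverse-engineer
theirs. Three permutation schemes: individuals anywhere (F_ST), individuals
within groups (F_SC), whole populations among groups (F_CT);
p = (#{perm ≥ obs}+1)/(n_perm+1). The identity
(1−F_CT)(1−F_SC) = (1−F_ST) holds to 1e−9 by construction.

## Bottleneck tests

The heterozygosity-excess test asks whether observed gene diversity He
exceeds its mutation-drift-equilibrium expectation Heq given the observed
allele count k: after a crash, rare alleles vanish faster than He decays.
Heq is obtained by simulating the single-population Kingman coalescent of
the sampled copies with stepwise mutations: strict SMM or a two-phase model
with a proportion p_ss of single-step changes and geometric multi-step
sizes parameterized by their variance (variance 12 ⇒ geometric parameter
0.25). θ is tuned by 20-step log-bisection until the mean simulated allele
count matches k; the Heq sample keeps replicates with exactly k alleles
(band widened to ±1, ±2 if acceptance starves, then a local He-on-k
regression as last resort, flagged). Loci are combined by a one-tailed
Wilcoxon signed-rank on the standardized differences DH = (He−Heq)/SD,
exact for ≤ 15 loci. The mode-shift indicator bins every allele's
within-population frequency into ten classes; the spectrum is L-shaped iff
the (0, 0.1] class is weakly maximal.

**Known property — liberal size.** The conditional distribution of He given
k is left-skewed (bounded above, long lower tail), so P(He > E[He|k]) ≈ 0.58
per locus even at perfect equilibrium; with 8 loci the exact one-sided
Wilcoxon at α = 0.05 then rejects in ≈ 8–10% of equilibrium populations
rather than the nominal ≤ 5% (measured here by simulation at θ ∈ {2, 5, 8},
n = 60 copies, and confirmed against an independent msprime oracle). Users
screening many populations should interpret isolated rejections accordingly
and apply a family-wise correction (the pipeline's qualitative check uses
Holm). Power is nonetheless substantial where it matters: a 100× crash 50
generations before sampling (≈ 0.25 × 2·Ne_new, where the excess signal
peaks) raises the rejection rate to ≈ 0.33 under the same conditions.

## Spatial structure

Geographic distances are great circles on a sphere of radius 6371.0 km.
IBD regresses F/(1−F) on the natural logarithm of distance (the
two-dimensional habit; RMA slopes are scale-covariant, so the log base only
rescales the slope). Mantel significance permutes one matrix's rows and
columns jointly, enumerating all n! relabelings when that is cheaper than
the requested permutation count. The RMA slope is sign(r)·s_y/s_x; its CI
is a percentile bootstrap that resamples *populations* (not pairs), keeping
the pair set internally consistent; pairs involving a population drawn
twice are dropped (zero distance, log undefined).

Barriers follow Monmonier's maximum-difference algorithm on a Delaunay
triangulation of coordinates projected equirectangularly with
cos(mean latitude) scaling (study regions are small enough that the
triangulation topology is insensitive to the projection). A barrier seeds
at the largest-distance uncrossed edge (ties → lowest edge index) and grows
from both sides, always crossing the adjacent triangle's larger-distance
edge, stopping at the convex hull or at an existing barrier; no virtual
boundary points are added, so barriers terminate at the hull. Successive
barriers are added until the triangulation graph minus crossed edges falls
into K_max components. Edge support is the fraction of locus-bootstrap
replicates (loci resampled with replacement, pairwise linearized F_ST and
barriers recomputed) in which any barrier crosses that edge. The bootstrap
unit is loci because SSR panels are small and the locus is the natural
resampling unit for a differentiation pattern.

## Coalescent scenario engine

Scenarios are rooted demographic histories over named populations:
divergence (derived population merges into its ancestor, backward in
time), admixture (a hybrid population dissolves into two parents with
probability r / 1−r per lineage) and stepwise Ne changes. Validation
guarantees a single root and rejects stranded lineages. Ancestry is
delegated to msprime (continuous-time coalescent, diploid samples, one
independent tree per locus — SSRs are unlinked); continuous migration is
deliberately absent from the scenario language (a known limitation of this
class of inference, which tends to underestimate divergence times).

Mutations follow the Generalized Stepwise Mutation model: step sizes
geometric with parameter P (P = 0 ⇒ strict SMM), direction symmetric,
folded into a bounded range of 40 contiguous allele states by mirror
reflection, root allele at the range midpoint. The model is expressed as a
40×40 transition matrix for msprime's matrix mutation engine, making
simulated datasets bit-exactly reproducible from (scenario, parameters,
seed). Per-locus mutation rates are gamma-distributed with fixed mean
2×10⁻⁴ per generation (shape 2) — the mean adopted from conifer SSR
practice — and the GSM P prior is uniform on [0.1, 0.3]; Ne priors default
to uniform [100, 10⁵] and event times to uniform [10, 10⁵] generations.
These defaults stand in for unavailable original settings and are wide
enough that posterior intervals stay interior to the prior.

The built-in scenario sets mirror the four standing questions for the
complex: hybrid origin vs recent divergence for the ×olcayana group; hybrid
origin vs divergence for the equi-trojani endemic; two topologies for the
species-level history; and a subspecies split with stable sizes vs an
Ne-change (historical bottleneck) in the isaurica lineage.

### Synthetic survey generator

`study_dataset` emulates the structure of the motivating survey: eight taxa
with realistic population counts (2/3/19/11/3/1/7/6), ~30 diploids per
population, 8 loci, hierarchical taxon divergences on the 10³–10⁴
generation scale with taxon Ne of 10⁴–10⁵ (magnitudes taken from the
published posterior modes), star-like population splits within taxa, 2%
missing calls (the survey's own rate is unstated; 2% is typical SSR
failure), and jittered coordinates near each taxon's real region (the
coordinates are synthetic stand-ins). What it does *not* emulate: null
alleles, genotyping error, allele-size homoplasy beyond the bounded range,
migration after divergence, and within-taxon isolation by distance — so
tests passing on these data validate the estimators and the qualitative
patterns (diversity ranking, taxon-level differentiation, equilibrium
bottleneck behaviour), not any numeric reproduction of the original
tables, whose genotypes are not public.

## ABC

Summary statistics per dataset: per population, the locus means of allele
count, gene diversity and allele-size variance; per population pair,
Weir–Cockerham θ̂, (δμ)² (squared difference of mean allele sizes) and the
shared-allele proportion |A∩B|/|A∪B| — six families, fixed order,
monomorphic loci contributing zeros. Rejection standardizes by the median
absolute deviation over the reference table and retains the closest 1% by
default (a retained-count alternative is exposed, since both conventions
are in circulation). Model choice fits an Epanechnikov-weighted multinomial
logistic regression (Newton iterations with a 1e−6 ridge; written
in-package because no installed library offers weighted multinomial fits
with an asymptotic covariance) and evaluates it at the observed vector;
confidence bounds come from the delta method, and complete separation
degrades gracefully to indicator probabilities. Parameter estimation uses
Beaumont's local-linear adjustment of log-transformed parameters (weighted
least squares on the standardized statistics), a weighted Gaussian-KDE mode
and weighted 2.5/97.5% quantiles.

Calendar conversion multiplies generations by 150 years with a ±-term of
50 years per generation, displayed in ky below 1 My and My above, rounded
to three significant figures half away from zero.

## Problem sizes used in the test suite

The validation suite scales the Monte-Carlo experiments to single-CPU
sizes chosen once: 500 equilibrium + 200 crash populations for the
bottleneck operating characteristics (equilibrium He distributions cached
by (k, n)); 100 stepping-stone replicates (8 demes × 10 diploids × 6 loci)
for IBD; 100 two-cluster layouts for barrier recovery; 2,000 loci for the
SMM equilibrium check; and 10,000 simulations per scenario, 7 loci and 12
diploids per population for ABC scenario recovery and coverage (20
pseudo-observed datasets each). The acceptance script uses a 2,000-per-
scenario table for its ABC stage and reports every quantity it computes.

## Known limitations

- The heterozygosity-excess test's liberal size (above) is a property of
  the published construction, not of this implementation.
- AMOVA df accounting under missing data is per-locus and documented, not
  identical to any particular legacy program.
- Multiple-barrier bookkeeping beyond the first barrier follows the
  documented construction (seed, extend, stop at hull/existing barrier);
  the legacy software's exact multi-barrier rules are not fully published.
- ABC results depend on prior choices; with the original study's priors
  unavailable, numeric reproduction of published posterior modes is out of
  scope.
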