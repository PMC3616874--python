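# Methods

This note documents the models implemented in `jointgp`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical decisions that matter for reproducing its output.

## Simulated populations

The simulator (`jointgp.simpop`) is a discrete-generation, forward-in-time
gamete sampler. A base population of Ne diploids starts at linkage
equilibrium with allele frequencies drawn U(0.05, 0.95) and random-mates
for a burn-in period, so LD is generated purely by drift against
recombination. Recombination uses the Haldane map function with no
interference: adjacent-interval recombination fractions are
c = ½(1 − e^(−2d)) for map distance d, and chromosome boundaries get
c = ½, so a single pass down the concatenated marker map simulates a
whole-genome meiosis. Markers are equally spaced on the genetic map with
physical positions at 1 Mb/cM; real bovine maps are deliberately not
reproduced.

At drift–recombination equilibrium the mean adjacent-pair r² is expected
near 1/(1 + 4Ne·c); the test suite checks the simulator against this
closed form within a factor of two (finite-sample estimation of r² is
upward-biased by roughly 1/(2n haplotypes), and equilibrium is approached,
not reached, in a finite burn-in).

Two populations are founded from disjoint samples of the base and drift
apart for a configurable number of generations — "shared ancestry a few
generations back". With zero divergence generations they are samples of
one gene pool, which pins the no-divergence limit of the LD-consistency
statistic near 1.

**Defaults** (all configurable in `SimConfig`): 2 chromosomes × 1 Morgan ×
500 markers, Ne = 100, 200 burn-in generations, split 50/50, 10 divergence
generations, 300 QTL, h² = 0.3, cross-population genetic correlation 0.8,
trend 0.1 genetic SD per birth year. The marker density is a scaled-down
stand-in for a 54K chip; Ne = 100 and L per chromosome match the values
used in the deterministic reliability discussion below.

### Trait architecture

QTL positions are sampled uniformly among markers. Each QTL receives a
*pair* of additive effects — the same biological trait expressed in the two
populations — drawn from a bivariate standard normal with correlation equal
to the target cross-population genetic correlation rG (at |rG| = 1 the
second effect vector is exactly proportional). Each trait's effects are
then rescaled so the true-breeding-value (TBV) variance in its own
population equals h², i.e. unit total variance once a (1 − h²) residual is
added. With several hundred QTL and similar allele frequencies the realized
TBV correlation tracks the effect correlation closely (tested within ±0.1).

### Families, selection and trend

Population A's structure mirrors a small national evaluation: bulls are
bred in birth-year cohorts, and a subset of them sires half-sib cow
families (family sizes drawn from a configurable range; daughters are
produced by actual gamete sampling, so opposing-homozygote checks and
pedigree-expected relationships hold exactly). Genetic trend is created by
truncation selection of sires on TBV. The selected fraction is *derived*
from the requested trend: with only sires selected, the per-cohort response
is half the sire selection differential, so the fraction f solves
i(f)/2 = trend, where i(f) = φ(Φ⁻¹(1−f))/f is the selection intensity. A
fixed selected fraction cannot honour an arbitrary trend target, which is
why the fraction is solved rather than fixed; trend 0 disables selection.

### Phenotypes

Deregressed proofs are generated directly from TBV with an exact
reliability contract: DRP = TBV + ε, Var(ε) = σ²g(1 − r²)/r², so
Cor²(DRP, TBV) = r² in expectation. This replaces deregression of
estimated breeding values — the deregression procedure of a national
evaluation is not reproducible, and direct generation makes the stated
reliability a testable input. Defaults: bull DRP reliability 0.90 (both
populations), cow DRP reliability 0.35. The cow value is an assumption
typical of single-lactation cow proofs; it is configurable and nothing
downstream depends on its exact value.

## Genotype handling

QC mirrors standard chip editing: markers are removed when MAF < 0.01
(strict inequality — boundary values are retained) or call rate below a
required explicit threshold (default 0.90), then animals with more than
10% missing genotypes are removed. The marker call-rate threshold is a
mandatory parameter rather than a constant because retention conventions
differ between pipelines; the default keeps markers called in at least 90%
of animals. Missing genotypes are excluded from allele-frequency and LD
computation and mean-imputed (2p, i.e. zero after centering) only inside G.

Cross-population comparisons of *signed* LD require both populations to
count the same allele at every marker; `harmonize_alleles` restricts to
shared markers, reflects dosages (2 − x) where the counted alleles differ,
and drops markers whose allele pairs cannot be reconciled by a swap. A
systematic flip negates the LD-consistency correlation — the test suite
demonstrates this antisymmetry.

## LD consistency

LD is computed by direct counting over pooled maternal and paternal
haplotypes. The consistency statistic correlates the *signed* r of
adjacent pairs (not r²) between populations, per chromosome; pairs
monomorphic in either population are excluded, chromosomes with fewer than
3 usable pairs are omitted, and the overall value is the unweighted mean
over chromosomes. Unweighted chromosome averaging is also used for the
marker-spacing summary (mean gap = span/(n−1) with the declared chromosome
length when provided); the acceptance tests exercise this arithmetic on
the 29 bovine autosomes at 54K-chip marker counts.

When phased haplotypes are unavailable, `em_pairwise_haplotype_freq`
estimates the two-locus haplotype frequency from genotypes by EM under
Hardy–Weinberg/random mating: only the double-heterozygote class is
phase-ambiguous, and its coupling/repulsion split is re-estimated from the
current frequencies each iteration (tolerance 1e−10 on Δf(AB)). Genome-wide
phasing is out of scope — simulated data are generated phased.

## GRM

VanRaden method 1: G = MM′/Σ2pᵢ(1−pᵢ) with column-centered allele counts.
For joint analyses the allele frequencies default to the pooled animal set
(per-population frequencies are available by flag); pooling is the natural
base when a single G spans both populations. A ridge (default 1e−6) is
added to the diagonal because with fewer markers than animals the centered
cross-product is rank-deficient. Note that centering by frequencies
computed from the same animals places the ones-vector exactly in the null
space of MM′ — the ridge is what makes Henderson systems solvable in that
common case.

## GBLUP and AI-REML

The mixed model fits one fixed mean per trait and a breeding value for
*every* animal in G (test animals carry no record and receive predictions
through G; the package verifies the identity
g_test = G_test,ref G_ref,ref⁻¹ g_ref numerically). Residual variances are
weighted per record by dᵢ = (1 − r²ᵢ)/r²ᵢ, the standard DRP weight that
makes record precision proportional to effective information; d(0.5) = 1
anchors the scale, and r² = 1 is floored at d = 1e−8 with a warning.

Variance components are estimated by average-information REML on the
record-space covariance V = Z(G0 ⊗ G)Z′ + R, which stays well-conditioned
because R > 0, rather than on the Henderson system. Numerical choices:

- **Parameterization:** log-variances and atanh(correlation), so estimates
  respect their bounds without explicit constraints. The correlation
  parameter is additionally clamped to |rG| ≤ 0.995: at the boundary G0
  becomes singular and the downstream Henderson system numerically
  unsolvable.
- **Updates:** Newton steps with the AI matrix (transformed through the
  Jacobian), elementwise step clipping at ±3, and step-halving so accepted
  steps never decrease the restricted log-likelihood; if no improvement is
  found along the AI direction the current point is returned as converged.
- **Start values:** half the phenotypic variance to each component per
  trait; genetic covariance starts at 0.5·√(σ²g1σ²g2).
- **Convergence:** relative change of every (co)variance below tol
  (default 1e−8; the pipeline uses 1e−6). Exhausting max_iter returns the
  best estimates flagged `converged=False`; phenotypes with zero variance
  return floored components, flagged.
- **Standard errors** come from the inverse AI matrix at the optimum.

In the two-trait across-population model the residual covariance is fixed
at zero: no animal has records for both traits, so it is not identifiable;
fixing it is the standard resolution. Solving the Henderson equations uses
Cholesky (LU fallback) with iterative refinement that keeps the best
iterate, because the G⁻¹ block can be ill-conditioned when markers <
animals; solutions are rejected above a relative residual of 1e−8.

The suite cross-checks this machinery against independent routes: dense
generalized-least-squares inversion, an MME-based EM-REML (Henderson trace
formulas), and centered-marker ridge regression (SNP-BLUP), whose GEBV
equal GBLUP's when the variance ratio is matched through Σ2pᵢ(1−pᵢ).

## Validation

Two designs:

- **Bull split:** the reference holds the proven sires (and the cows);
  candidate bulls without genotyped daughters form the test set, excluding
  any with maximum genomic relationship ≥ 0.45 to a reference bull. The
  0.45 default sits between first-degree kin (~0.5) and half-sibs (~0.25),
  so sons are excluded and unrelated candidates retained (tested over
  seeds). Bull GEBV and DRP are detrended on birth year before
  correlating, because selection trend inflates the naive correlation.
- **Cow cross-validation:** whole half-sib families are assigned to folds
  (13 families over 5 folds → 3/3/3/2/2), sizes balanced greedily, so a
  test cow never has paternal half-sibs in the reference. Reliability is
  computed on GEBV pooled over the folds. Variance components are
  estimated once on the full reference and reused across folds — only the
  record set changes per fold, and re-estimating five times would
  dominate runtime without changing the comparison.

Realized reliability is Cor²(GEBV, DRP)/mean(r²_DRP). It is deliberately
not clamped: GEBV ≡ DRP at mean reliability 0.5 gives 2.0, which is the
statistic's contract, not a bug.

The deterministic expectation uses Me = 2NeL effective chromosome
segments, k = 1/ln(2Ne), λ = Me·k/h², a = 1 + 2λ/N and
E[r²] = 1 − λ/(2N√a)·ln[(1+a+2√a)/(1+a−2√a)]. Natural logarithms are used
in both k and the main term; under this convention the formula gives 0.175
at L = 30, Ne = 100, N = 1500, h² = 0.50 (h² here is the reliability of
the reference phenotypes, not the trait heritability), the worked value
frozen into the acceptance check. The function is strictly increasing in N and h² and
decreasing in Ne, verified on grids.

## Scenario defaults and problem sizes

The orchestrated scenario (`ScenarioConfig`) defaults to population A =
40 bulls (birth years 1993–2002) + 13 half-sib families totalling 416 cows
(2001–2006), population B = 600 bulls (1974–2008), 2 × 500 markers. These
sizes preserve the design of the motivating setting — a small mixed
reference next to a bull reference an order of magnitude larger — at a
scale where a full scenario (simulation, QC, LD, two REML fits, bull and
five-fold cow validation) completes in seconds, so directional claims can
be tested across many seeds. `simpop` itself accepts the full-size
configuration (thousands of bulls, 54K markers) if one is willing to wait.

All randomness flows from one root seed through named `SeedSequence`
sub-streams (base population, split, trait draw, families, B-population,
phenotypes, folds, parentage panel, cow removal), so stages are
individually reproducible.

## What passing tests do and do not show

The simulator emulates drift-generated LD, recent shared ancestry,
family structure, selection trend, and reliability-weighted DRP. It does
**not** emulate mutation, realistic bovine map heterogeneity, genotyping
error, imputation error, population admixture or genotype-by-environment
structure beyond what an imperfect cross-population genetic correlation
captures. Absolute reliabilities on simulated data are therefore not
comparable to field values — with only ~2 Morgans of genome, Me is small
and reliabilities run high. What the tests do establish is directional and
structural: the joint reference raises test-set reliability when (and only
when) the populations share ancestry and a nonzero genetic correlation;
LD consistency declines with divergence time; the estimators agree with
independent oracles; and every statistic honours its stated contract.

## Known limitations

- AI-REML forms dense n×n record-space matrices; practical up to a few
  thousand records per fit on one core.
- The EM haplotype-frequency fallback assumes Hardy–Weinberg within the
  sample; strong family structure biases it slightly.
- `read_genotypes` for PLINK text re-derives the counted allele from the
  observed alleles (alphabetical convention), so monomorphic markers can
  change orientation on a write/read round trip; harmonization handles
  this downstream.
- The two-trait model supports exactly two populations; extending to more
  requires a general G0 parameterization not implemented here.
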