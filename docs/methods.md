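# Methods

This note documents the models, algorithms and design choices behind
`ssgblup`: what each stage computes, which knobs matter, what the synthetic
data do and do not emulate, and the numerical conventions that make runs
reproducible.

## The animal model and the three methods

All analyses fit the univariate linear mixed model

    y = Xβ + Z₁c + Z₂a + e,
    Var(a) = Δ σ²ₐ,  Var(c) = I σ²_cg,  Var(e) = I σ²ₑ,

where y are trait records (kg), X carries the fixed effects (intercept,
sex, dam age in days; plus management group and an age covariate for
post-weaning traits), c are random contemporary-group (CG) effects for
herd × birth-year × birth-season classes, and a are additive genetic
values. The three evaluation methods differ only in Δ and in which animals
are evaluated:

| method  | Δ | animals in a |
|---------|---|--------------|
| BLUP    | A (pedigree) | all pedigree animals |
| GBLUP   | G (genomic)  | genotyped animals only |
| ssGBLUP | H (single-step blend) | all pedigree animals |

Heritability is reported as h² = σ²ₐ/(σ²ₐ + σ²_cg + σ²ₑ), i.e. the CG
variance is counted as part of the phenotypic variance, and the percentage
share of each component uses the same denominator. Maternal genetic
effects are outside the model's scope.

## Relationship matrices

**A** is built by the tabular method over a parents-first (topological)
ordering; the diagonal is 1 + F. **A⁻¹** never forms A: inbreeding
coefficients come from the Meuwissen–Luo ancestor-tracing algorithm
(O(ancestors) per animal) and feed Henderson's rules, in which each
(animal, sire, dam) triple contributes the [1, −½, −½] pattern scaled by
the inverse Mendelian-sampling variance
dᵢ = 1 − ¼(1+F_s) − ¼(1+F_d). The product `a_inverse(ped) · tabular_a(ped)`
is checked against the identity in the test suite (the two routines share
no code path beyond the pedigree container).

**G = WW′/q** uses additive codes 0/1/2 with each marker column centred on
its observed mean and divided by its *sample* standard deviation (divisor
n−1). That convention forces trace(G) = n−1 exactly, hence an average
diagonal of (n−1)/n ≈ 1 — the same scale as A. The population-SD
alternative would be a one-line change; the sample-SD form is the package
default and the one all identities in the tests assume. QC order is
enforced: G refuses matrices with missing entries or zero-variance
columns.

**Blending.** Because G is expressed relative to the observed genotyped
sample while A_gg (the genotyped submatrix of A) is relative to the
pedigree base, the two are put on one scale by the affine map Gₐ = βG + α
with (α, β) solving the 2×2 system matching the mean diagonal and the
overall mean of Gₐ to those of A_gg. The system is singular exactly when
Avg(diag(G)) = Avg(G) (e.g. a constant matrix); that raises a dedicated
error. The solved blend reproduces both moments to 1e−10 by construction.

**H⁻¹** is assembled in place on the pedigree ordering:
A⁻¹ plus (Gₐ⁻¹ − A_gg⁻¹) added on the genotyped block. If the smallest
eigenvalue of a block is below 1e−8, a 1e−8 diagonal jitter is added once
and logged; a block that stays singular raises with the offending
eigenvalue. With no genotyped animals the correction block is empty and
H⁻¹ is bit-identical to A⁻¹.

All matrices are dense `float64`. The package targets desk-scale
populations (up to a few thousand animals, ~10⁴ markers), where dense
linear algebra is simpler and faster than sparse bookkeeping; this is a
deliberate scale decision, not a limitation of the algorithms.

## Gibbs sampler

Variance components and EBVs come from a conjugate Gibbs sampler with flat
priors on β and scaled-inverse-chi-square priors on the three variances.
The hyperparameter convention is df = 5 per component with the scale set so
the prior mode equals R²ₖ·var(y), default split R² = 0.25/0.25/0.5 across
(additive, CG, residual); both df and split are configurable, and any
variance can be pinned for analytic checks.

Mechanism (the posterior is the same as for any exact Gibbs scheme; only
the mechanics differ): the model is reparameterised through the genetic
values of recorded animals, g = Z₂a, with Var(g) = K σ²ₐ and
K = Δ[rec, rec]. One eigendecomposition K = UΛU′ per fit rotates the whole
system by U′; in the rotated space the genetic coordinates have independent
normal full conditionals, and because indicator blocks keep orthogonal
columns under rotation, the CG block's full conditional stays diagonal too.
Each sweep costs a handful of vectorised O(n·n_cg) operations, so a
50,000-iteration chain on ~2,000 records runs in seconds after the one-off
eigendecomposition. Null eigenvalues of K (singular G, redundant animals)
are excluded from both the update and the σ²ₐ degrees of freedom.
Breeding values of animals *without* records are recovered by the exact
conditional-mean back-solve â = Δ[:, rec] K⁺ ĝ. The sampler assumes one
record per animal — true for birth, weaning and yearling weights — and
raises on repeated records rather than silently mishandling them.

Chain defaults mirror the headline analysis: 25,000 kept iterations after
25,000 burn-in, thinned by 10 (2,500 stored samples). Cross-validation
uses a shorter default (5,000 + 5,000, thin 5) because the partition loop
repeats the fit hundreds of times; both are configurable. The reported
"SE" of each variance component is its posterior standard deviation.
Posterior means of h² use the ratio of posterior-mean components (matching
the usual tabular presentation); a per-sample alternative is available.

Two caveats worth knowing: the overall EBV level rides on a slowly mixing
intercept/genetic-mean trade-off (rankings and centred EBVs mix much
faster), and ssGBLUP run through H = inv(H⁻¹) agrees with BLUP only to
Monte-Carlo precision when nobody is genotyped, because the inversion
perturbs A at the 1e−12 level and chains amplify bit differences.

## Editing rules

Phenotype QC applies, in order: (1) removal of records beyond ±k sample
standard deviations from the raw mean (k = 3; single pass — mean and SD
are not re-estimated after removals); (2) removal of records missing
required covariates, counted per field; (3) removal of animals with no
pedigree path to any genotyped animal, decided by connected components of
the undirected parent–offspring graph (exactly the nonzero pattern of A,
computed without forming A); (4) CG construction as herd ⊕ year ⊕ season
with the fixed Julian windows 80–171 spring, 172–264 summer, 265–354
autumn, 355–366 and 1–79 winter (day 366 falls in winter); (5) removal of
CGs with fewer than two records or zero within-group variance. The
composition is order-dependent and the QC report lists rules in the order
applied, with removed + surviving = input.

Genotype QC: intersect the two chip panels (each animal keeps its own
panel's calls; conflicting duplicate calls are an error), drop markers
with call rate strictly below 0.95, estimate θ̂ⱼ from pre-imputation calls
as (Σ codes)/(2·non-missing), impute missing calls with 2θ̂ⱼ (mean
imputation preserves column means, so the θ̂ used downstream is unchanged),
then drop monomorphic markers and those with min(θ̂, 1−θ̂) strictly below
0.04. Threshold comparisons carry a 1e−12 guard so ratios of small
integers sit on the intended side of the boundary. Per-individual
missingness is reported but no individuals are removed by default (a
threshold can be supplied).

## Cross-validation protocol

Testing sets are drawn from the genotyped, phenotyped animals:
round(0.2·n) animals (half away from zero), sampled without replacement,
100 independent partitions by default. The same testing ids are used by
all three methods; training is the remaining genotyped phenotyped animals
for GBLUP and all other phenotyped animals for BLUP/ssGBLUP — so the
methods solve an identical prediction task with different information.
Testing phenotypes never enter a training response; testing animals remain
in the relationship structures, which is how their EBVs are predicted.
Adjusted phenotypes y* = y − Xβ̂ − Z₁ĉ use the posterior means *of the
training fit of the same method* (no leakage, no cross-method borrowing);
a CG unseen in training contributes ĉ = 0 with a logged warning. Undefined
correlations (constant EBVs or y* in a testing set) are recorded as
missing, excluded from means and the SE divisor rather than counted as
zero. Summaries report mean, SD and SE = SD/√(valid partitions) — SD/10 at
the standard 100 partitions.

## Synthetic data

The generator exists so that every stage can be exercised against known
truth; it emulates a multi-herd purebred cattle study:

* **Pedigree** — discrete generations from a founder cohort; each
  generation uses a limited pool of breeding sires (`sire_fraction`,
  default 0.08 of available males), every dam is mated to one pooled sire,
  and litter sizes are Poisson. The limited sire pool produces the large
  paternal half-sib families typical of cattle; this family structure is
  what identifies σ²ₐ in the animal model, and with near-random mating the
  additive variance becomes badly identified. Herds are assigned
  uniformly; birth years step one generation per calendar step across
  `year_range`; birth days are uniform over 1–365.
* **Genotypes** — gene dropping: founder alleles Bernoulli(θⱼ) with θⱼ
  uniform in `founder_allele_freq_range`, one allele inherited per parent
  per locus, loci independent (no linkage or LD). Markers are split into
  chip-A-only/chip-B-only/shared panels; each genotyped animal sits on one
  chip and misses the other chip's private markers structurally, plus
  random missing calls at `missing_call_rate`. The genotyped subset is
  drawn from the latest generations, mirroring the recency of genotyping
  in real programmes and guaranteeing pedigree connectedness.
* **True breeding values** — the infinitesimal recursion
  aᵢ = ½(a_s + a_d) + mᵢ with Mendelian-sampling variance
  ½σ²ₐ(1 − (F_s+F_d)/2) (founders N(0, σ²ₐ)). This makes A·σ²ₐ the exact
  covariance of the truth regardless of marker density, so
  parameter-recovery tests have a clean target; genotypes and breeding
  values are deliberately independent.
* **Phenotypes** — one record per animal: configured fixed effects
  (kilograms; units chosen for realism, with no effect on any statistic),
  CG effects iid N(0, σ²_cg) on the same herd-year-season labels the QC
  stage later reconstructs, and iid residuals. Dam age is the true
  birth-date difference when the dam is known.

Two canned configurations set the study conditions. `braunvieh_like()`:
120 founders, 9 generations over 1998–2016, 8 herds with ~10–15 breeding
sires per generation (inbreeding accumulates at roughly 1% per generation,
as in closed herd books), ~20% genotyped (~300 animals) on two chips
sharing 80% of ~16K simulated markers, 2% missing calls, truth variances
(3.323, 6.348, 3.099) kg² — h² = 0.26 with the CG explaining ~50% of
phenotypic variance, inside the bands reported for birth weight in
comparable populations. `recovery_config()`: ~2,000
records in ~100 CGs with true shares 25/45/30 (h² = 0.25), used by the
20-replicate parameter-recovery study.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linkage and LD (so marker-density effects
on GBLUP accuracy are not represented), selection or assortative mating
(no genetic trend; year effects and genetic change are unconfounded by
design), maternal genetic or permanent-environment effects, genotyping
error, and heterogeneous residual variances across herds.

## Problem sizes and numerical conventions

Tests run at deliberately compact sizes chosen to make their statistical
assertions sharp yet quick: the recovery study uses 20 replicates of
~2,000 records at cross-validation chain length; the CV monotonicity check
uses 20 partitions of a ~300-record population with short chains; oracle
checks on A⁻¹/H⁻¹ use 10–50 random pedigrees up to n = 300. The
acceptance script runs the study-scale population (~1,500 animals, 16K
markers, full 25K+25K chains) for the headline fits and a compact
˜350-record population for its 100-partition validation. Tolerances:
exact linear-algebra identities at 1e−8–1e−12; Monte-Carlo quantities at
2–3 standard errors of their sampling distribution. Ties and boundaries:
threshold comparisons use a 1e−12 epsilon; testing-set sizes round half
away from zero; day 366 is winter. All randomness flows from a single
seed through named, independent substreams (simulation, gene drop,
phenotypes, partitioning, each MCMC chain), so changing one consumer
never perturbs another and reruns are byte-identical.

## Known limitations

* Dense matrices bound the practical population size (~5,000 animals).
* One record per animal; repeatability models are out of scope.
* The sampler's eigendecomposition route assumes Δ is available as a
  covariance; ssGBLUP therefore materialises H = inv(H⁻¹) once per
  analysis instead of working from H⁻¹ in the mixed-model equations.
* Univariate analyses only; no maternal effects; no genomic imputation
  between chip densities beyond the shared-marker intersection.
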