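# ssgblup

Pedigree, genomic and single-step BLUP evaluation for beef-cattle growth
traits, with a synthetic-data generator that makes the whole pipeline
testable end to end.

## The problem

Genetic evaluation of a herd-book population predicts each animal's
breeding value (EBV) — its additive genetic merit — from phenotypes,
pedigree and, increasingly, SNP genotypes. When only a few hundred animals
of a large pedigree are genotyped, three methods compete, differing only in
the covariance structure **Δ** of the additive effects in the animal model

```
y = Xβ + Z₁c + Z₂a + e,
Var(a) = Δ σ²ₐ,   Var(c) = I σ²_cg,   Var(e) = I σ²ₑ
```

* **BLUP** — Δ = **A**, the pedigree numerator relationship matrix
  (diagonal 1 + F);
* **GBLUP** — Δ = **G** = WW′/q, the marker-realized relationship matrix
  from centered, standardized genotype codes (genotyped animals only);
* **ssGBLUP** — Δ = **H**, the single-step matrix combining both, whose
  inverse is assembled directly:

```
H⁻¹ = A⁻¹ + [0 0; 0 Gₐ⁻¹ − A_gg⁻¹],   Gₐ = βG + α,
```

with (α, β) solving `Avg(diag(G))β + α = Avg(diag(A_gg))` and
`Avg(G)β + α = Avg(A_gg)` so the genomic and pedigree matrices sit on one
scale. Fixed effects β (sex, dam age, management, age covariates) and a
random contemporary-group effect c (herd × birth-year × birth-season)
complete the model. Variance components, heritability
h² = σ²ₐ/(σ²ₐ+σ²_cg+σ²ₑ) and EBVs are estimated by a conjugate Gibbs
sampler; predictive ability is compared by repeated random 80/20
partitions in which the same testing animals are predicted by all three
methods and scored by the Pearson correlation between their adjusted
phenotypes (y − Xβ̂ − Z₁ĉ from the training fit) and their EBVs.

The package implements every stage: phenotype editing (±3 SD outliers,
completeness, pedigree connectivity to the genotyped set, contemporary-group
construction and filters), SNP QC (two-chip panel intersection, call-rate
≥ 95%, allele frequencies, 2θ̂ mean imputation, MAF ≥ 0.04), relationship
matrices (tabular A, Meuwissen–Luo/Henderson A⁻¹, VanRaden-style G, the
α/β blend, H⁻¹), the Gibbs animal model, matched cross-validation, plain
TSV file formats, and a `ssgblup` command-line interface. A gene-dropping
simulator with an infinitesimal-model truth generates populations with the
same statistical structure, so parameter recovery and method behaviour can
be verified against known truths.

## Worked example

```python
import ssgblup as s
from ssgblup.animal_model import McmcConfig, ModelSpec, build_design, fit_animal_model

cfg = s.braunvieh_like(seed=1, n_markers=4000)   # multi-herd synthetic population
ped = s.simulate_pedigree(cfg)                   # 1,631 animals, 10 generations
drop = s.gene_drop_genotypes(ped, cfg)           # 326 genotyped on two chips
records = s.simulate_phenotypes(ped, cfg, drop.true_values)

qc, report = s.run_phenotype_qc(records, ped, drop.genotyped_ids)
geno, _, _ = s.run_genotype_qc(*s.split_panels(drop))

a = s.tabular_a(ped)
g = s.genomic_relationship(geno)
agg = s.extract_agg(a, g.ids)
coeffs = s.solve_blend(g, agg)
print(f"alpha={coeffs.alpha:.4f} beta={coeffs.beta:.4f}")
h = s.h_from_h_inverse(s.assemble_h_inverse(s.a_inverse(ped), agg,
                                            s.blend_ga(g, coeffs), g.ids))

spec = ModelSpec("BW", method="ssGBLUP")
fit = fit_animal_model(build_design(qc, spec, h.ids), h, spec,
                       McmcConfig(n_iterations=5000, burn_in=5000, thin=5, seed=1))
print({k: round(v, 2) for k, v in fit.var_mean.items()},
      "h2 =", round(s.heritability(fit), 3))
```

prints

```
alpha=0.2283 beta=0.8716
{'sigma_a': 2.37, 'sigma_cg': 5.91, 'sigma_e': 3.37} h2 = 0.203
```

— the blend nudges G onto A_gg's scale (β ≈ 0.87, α ≈ 0.23 absorb the
inbreeding the closed pedigree has accumulated relative to the genotyped
sample's own base), and the single-step fit tracks the simulation truths
(3.323, 6.348, 3.099) kg², h² = 0.26, with single-replicate posterior
spreads of a few tenths of a kg² per component (posterior SDs 0.35, 0.57,
0.23). Averaged over replicates the estimates are unbiased to within a few
percent — that is what the multi-replicate recovery test in the acceptance
suite checks.

A quick end-to-end run from the shell (a compact synthetic population with
shorter chains and 20 validation partitions, about a minute):

```bash
ssgblup --seed 1 run-all --outdir demo-run
```

writes `qc_phenotypes.tsv`, `qc_genotypes.tsv`, `matrix_summaries.tsv`,
`variance_components.tsv` (value / posterior SD / % share per component and
method, plus h²), `cv_correlations.tsv`, bar-chart data and a structured
`run_log.yaml`.

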