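# protmr

Observational and one-sample Mendelian-randomization (MR) scans of a
high-dimensional plasma proteome against a continuous exposure (body mass
index), with correlation-aware multiple testing, protein clustering and
disease-class enrichment — plus a synthetic-cohort generator with known
causal structure for validating every stage.

## Who this is for

Epidemiologists and biostatisticians who want to estimate the causal
footprint of adiposity (or any continuous exposure with a polygenic
instrument) across thousands of correlated protein traits, and to check
the machinery on simulated cohorts where the truth is known.

## The model

For individual *i* with effect-allele dosages *g<sub>ij</sub>* and source-GWAS
weights *β<sub>j</sub>* over *M* instrument SNPs, the weighted genetic risk
score is the average per-SNP effect

&nbsp;&nbsp;GRS<sub>i</sub> = (Σ<sub>j</sub> g<sub>ij</sub> β<sub>j</sub>) / M.

Each protein trait *p* (residualised on nuisance covariates, then rank
inverse-normal transformed) is analysed two ways against the exposure *X*
in SD units:

- **Observational**: OLS of protein on *X* adjusted for age and sex
  (model 1) and additionally smoking and alcohol (model 2);
- **MR**: exactly identified two-stage least squares with the GRS as the
  single instrument, β̂ = cov(GRS, protein) / cov(GRS, X), with
  heteroskedasticity-robust sandwich standard errors.

A valid instrument removes confounding: if a latent confounder *U* loads on
the exposure with *c<sub>x</sub>* and on a protein with *c<sub>p</sub>*, the
observational slope converges to β + c<sub>x</sub>c<sub>p</sub>/Var(X)
(omitted-variable bias) while the MR slope stays at the causal β.

Multiple testing uses the effective number of independent traits: Spearman
correlations, complete-linkage clustering on distance 1 − |r|, a static tree
cut at height 0.2 (so any pair with |r| ≥ 0.8 collapses), and the
family-wise threshold 0.05 / m_eff. Signal detection clusters proteins by
PCA (proteins as observations) + a k-means scan, compares clusters by
one-tailed rank-sum tests on |β|/SE, and tests the top cluster for
disease-class enrichment by fold enrichment
(count/list_total)/(pop_hits/pop_total) with the conservative EASE
(overlap-minus-one hypergeometric) tail probability.

Analytic MR power for a standardized outcome is
Φ(|β|·√(n·R²<sub>GX</sub>) − z<sub>1−α/2</sub>).

## Worked example

`examples/03_observational_vs_mr.py` simulates 20 000 individuals, one
protein with no causal BMI effect but a shared confounder (loadings 0.5 and
0.5) and one with a causal effect of 0.5 SD per SD:

```
confounded null  obs beta +0.244 (SE 0.007)   MR beta -0.055 (SE 0.043)
causal 0.5       obs beta +0.499 (SE 0.006)   MR beta +0.490 (SE 0.036)
first-stage F = 590.6
```

The null protein's observational slope sits at the omitted-variable value
0.5 × 0.5 = 0.25, while its MR estimate is indistinguishable from zero; the
causal protein is recovered by both estimators, MR with wider error bars.
The other scripts in `examples/` walk through cohort simulation, instrument
validity, the m_eff correction, cluster enrichment, and the full pipeline.

A full-scale end-to-end run (`protmr run --seed 3 --outdir out/`) simulates
2 737 individuals, 654 SNPs and 4 034 block-correlated proteins, and under
the default generator reports, e.g., m_eff = 3 693 (threshold 1.35 × 10⁻⁵),
1 425 observational model-1 hits against 52 MR hits — the expected signature
of confounded observational scans paired with a modest-strength instrument.

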