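# Methods

## Problem and overall design

The package estimates the effect of a continuous exposure — body mass
index, self-reported, in kg/m² — on a panel of thousands of aptamer-based
plasma protein measurements, in two frameworks run side by side: plain
covariate-adjusted linear regression ("observational") and one-sample
Mendelian randomization with a polygenic score as instrument ("MR").
Divergence between the two, protein by protein, is the quantity of
scientific interest: confounding and reverse causation move the
observational estimate but not (to first order) the MR estimate.

Because no individual-level cohort ships with the package, every stage is
validated on synthetic cohorts whose causal structure is known exactly.
The generator is first-class, tested code; its defaults are fixed study
conditions, not tuning knobs.

## Pre-processing

Protein traits are residualised on nuisance covariates (default: age and
sex) by per-trait OLS and the residuals mapped through the rank
inverse-normal transform (RINT) — in that order. RINT uses
Φ⁻¹((rank − 0.5)/n) with average ranks for ties; the Blom offset
(rank − 3/8)/(n + 1/4) is available via `rint_offset="blom"` but the
half-offset is the default because it is the variant used by the
GenABEL-family `rntransform` utilities common in this literature. Ties take
average ranks deterministically rather than random splitting:
reproducibility outweighs fidelity to an unspecified upstream choice.
The exposure gets the same RINT, so downstream slopes read as SD protein
per SD exposure. The observational models re-adjust for age and sex even
though proteins were pre-adjusted — residualise-then-transform can
re-introduce small correlations, and the double adjustment removes them.

A protein exactly explained by the covariates has residuals that are pure
numerical noise; its adjusted trait is set to zero rather than
rank-transforming noise.

## Genetic risk score and instrument validity

The score is the weighted dosage sum divided by the number of SNPs, i.e.
the average per-SNP effect on the exposure; it is deliberately left
unstandardized (validity tables report "per 1-unit GRS"), since the 2SLS
estimate is invariant to instrument scaling. Validity diagnostics are
simple OLS fits of the exposure and of each measured covariate on the
score (β, SE, P, adjusted R², F), plus a Shapiro–Wilk normality check of
the score (delegated to the standard Royston implementation; n is capped
at 5 000 by that algorithm, and a fixed subsample is used beyond it).
No dosage imputation is performed: synthetic cohorts are complete, and
mean imputation for real data is a config hook left off by default.

## Estimators

Observational scans solve one shared design per model with closed-form
OLS over all proteins at once (classical SEs, two-sided t tests); this is
numerically identical to per-protein `statsmodels` fits (pinned by tests)
and ~100× faster at 4 000 traits. Missing covariates are handled by
listwise deletion per model, so model 2 (adding smoking and alcohol,
ordered categories entered numerically) runs on fewer individuals.
Covariable scans are univariable. Note that scanning a covariate that was
already residualised out of the proteome is structurally conservative
(P ≈ 1); the scan is still reported because the analysis models re-adjust
for those covariates.

MR is exactly identified IV: with instrument block Z = [1, GRS] and
regressor block X = [1, exposure], β̂ solves (Z′X)b = Z′y, which is the
Wald covariance ratio. Standard errors are the IV sandwich
A(Z′diag(e²)Z)A′ with A = (Z′X)⁻¹ and structural residuals e computed
with the observed exposure; HC1 (n/(n−k) rescaling) is the default and
HC0 available, the choice being essentially immaterial at n ≈ 2 700.
P-values use the normal approximation, the common choice for IV
inference; no extra covariates enter the MR stages by default because
exposure and proteins are already transformed, but a covariate block can
be passed into both stages. First-stage strength is reported as
F = (n−2)R²/(1−R²).

Analytic power uses the non-centrality approximation
power = Φ(|β|√(nR²) − z₁₋α/₂), which tends to α/2 as β → 0 (the upper
tail of the two-sided size). Its companion empirical check simulates
(instrument, exposure, protein) triples with a Gaussian instrument — the
average over hundreds of independent SNPs is normal to excellent
approximation, which is also what the Shapiro–Wilk diagnostic verifies on
realistic scores — and draws the structural error at unit SD, matching the
formula's approximation of the residual SD by the (standardized) outcome
SD. If instead the outcome is forced to exactly unit variance, the formula
is conservative by roughly four percentage points at β = 0.33.

## Multiple testing

Spearman correlations between adjusted proteins feed a complete-linkage
dendrogram on distance 1 − |r| cut statically at height 0.2. Complete
linkage is chosen because it makes the cut literal — every within-cluster
pair satisfies |r| ≥ 0.8 — whereas average linkage (available via config)
only satisfies it on average. Absolute correlation is used so strongly
anti-correlated aptamers also collapse; the sign convention in verbal
descriptions of "correlation cut-offs" is ambiguous, and collapsing both
signs is the conservative reading. Each cluster counts once toward m_eff
and is represented by its medoid (max mean |r| to cluster-mates); the
threshold is exactly α/m_eff.

## Clustering and enrichment

PCA is run on the protein × individual matrix (proteins as observations,
each protein's profile centred), so principal-component scores embed
proteins, not people. The scree elbow (largest drop in explained-variance
fraction, scanned over the leading 20 components) suggests the number of
PCs; it is a heuristic for visual scree reading and can be overridden with
an explicit `n_pcs`. k-means runs for every k in the configured range
(default 2–20, 10 restarts, seeded); the chosen k is the smallest whose
between-cluster/total sum-of-squares ratio is within 0.01 (configurable)
of the ratios at both k+1 and k+2 — an explicit version of "smallest k at
the plateau". If no plateau occurs inside the range the largest-ratio k is
used and the full scan table is always emitted so a human can force k.

Cluster effect strength is the median (and IQR) of |β|/SE within the
cluster, compared one-tailed (greater) by Mann–Whitney rank-sum both
against the pooled set of all proteins (own members included — the
comparison is against the overall estimate, not the complement) and
pairwise against every other cluster.

Enrichment of a protein list against the full measured background uses
fold enrichment (count/list_total)/(pop_hits/pop_total) and the EASE
score: the one-tailed hypergeometric tail computed after removing one
protein from the list-in-class overlap, which is always at least the plain
Fisher tail and equals 1 when the overlap is a single protein. Totals
count only proteins carrying at least one class annotation (the mappable
universe), which is how category-enrichment tools report List Total and
Population Total; plain Fisher is available via flag. Bonferroni
multiplies by the number of classes actually tested, capped at 1. Because
the population includes the list itself, a class seeded at rate ratio F
inside a cluster of weight w has expected fold-enrichment statistic
F/(wF + 1 − w), not F — tests use this closed form.

## Synthetic cohorts

Defaults (all chosen once, as study conditions): n = 2 737 individuals,
654 instrument SNPs, 4 034 protein traits. Dosages are Binomial(2, MAF)
with MAF ~ U(0.05, 0.5), independent across SNPs — the score treats SNPs
additively, so LD modelling would add nothing to estimator validation.
The standardized exposure is

X = Σγⱼgⱼ + covariate effects + c_x·U + ε,  Var(X) = 1,

with γ proportional to the GWAS weights and scaled so the weighted score
explains exactly the target R² (default 0.028) in expectation; BMI is then
25.9 + 4.8·X kg/m². Covariate effects on X default to +0.17 SD for age
(per SD) and male sex, +0.05 smoking, −0.05 alcohol — signs and rough
magnitudes typical of adult cohorts — and smoking/alcohol values are
masked at 2.3%/11.5% to exercise per-model listwise deletion. The latent
confounder U is standard normal with exposure loading 0.4 by default.

Each protein is β_p·X + c_p·U + block-correlated noise scaled to unit
total variance; requesting loadings whose systematic variance reaches 1
raises an "infeasible variance budget" error. By default 10% of proteins
are causal with β ~ N(0, 0.3²) (clipped at ±0.65, about the strongest
effect sizes seen on aptamer panels) and confounder loadings
c_p ~ N(0, 0.2²) clipped at ±0.4. Correlated blocks of five proteins at
r = 0.9 cover ~12.5% of the panel, putting m_eff near 90% of the trait
count, the regime observed on real aptamer panels.

What the generator does **not** emulate: linkage disequilibrium and
population stratification, genotyping or measurement error, non-normal
protein distributions (aptamer RFUs are heavy-tailed before
transformation; the generator produces the post-QC, near-Gaussian regime),
assay batch structure, and selection into the cohort. Passing tests
therefore demonstrate estimator correctness under the assumed structural
model, not robustness to those real-data pathologies.

Annotation simulation assigns classes independently per protein at a
background rate, with one chosen class enriched by a given rate ratio
inside a given protein set.

## Pipeline determinism and problem sizes

The pipeline forks a master seed per stage with `SeedSequence.spawn`, so
reruns are bit-identical and changing one stage's draws cannot perturb
another's. A full-scale run (2 737 × 654 × 4 034) completes in well under
a minute; the test suite exercises the same code paths at reduced sizes —
e.g. parameter recovery uses 200 replicate cohorts at n = 2 737 with 60
SNPs, since the MR sampling distribution depends on the instrument R²
(calibrated identically) rather than on the SNP count, and null
calibration uses uncorrelated proteins so the binomial error band for the
P < 0.05 fraction is exact.

## Known limitations

- One instrument, one exposure: no pleiotropy-robust estimators
  (MR-Egger, weighted median) and no multi-exposure models.
- Dosage TSVs only; no PLINK/VCF parsing.
- The scree and plateau heuristics formalise what is usually a visual
  choice; forced overrides are provided for a reason.
- The percentage column that some enrichment tools print is not
  reproduced; its denominator is internal to those tools.
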