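"""Weighted genetic risk score and instrument-validity diagnostics.

The score multiplies each SNP's effect-allele dosage by its source-GWAS
beta, sums over SNPs and divides by the number of SNPs, so one unit of GRS
is the average per-SNP effect on the exposure.  Validity diagnostics fit
simple OLS of each trait (exposure and candidate confounders) on the score
and report beta, SE, P, adjusted R^2 and the F statistic; an instrument is
credible when it predicts the exposure strongly (large F) but none of the
confounders.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclasses.dataclass
class GRSResult:
    score: pd.Series
    n_snps_used: int
    validity: pd.DataFrame | None = None
    normality: tuple[float, float] | None = None


def build_grs(cohort) -> pd.Series:
    """Per-individual weighted GRS: (sum_j dosage_ij * beta_j) / M."""
    weights = cohort.snp_meta["weight"].reindex(cohort.dosages.columns)
    if weights.isna().any():
        bad = weights.index[weights.isna()][0]
        raise ValueError(f"missing GWAS weight for SNP {bad!r}")
    m = len(weights)
    score = cohort.dosages.to_numpy() @ weights.to_numpy() / m
    return pd.Series(score, index=cohort.ids, name="grs")


def _simple_ols_row(trait: pd.Series, score: pd.Series) -> dict:
    """One validity row: OLS of trait on score (statsmodels fit)."""
    joined = pd.concat([trait.rename("y"), score.rename("g")], axis=1).dropna()
    n = len(joined)
    if n < 4:
        raise ValueError("too few complete observations for validity model")
    y = joined["y"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"trait {trait.name!r} has zero variance")
    X = sm.add_constant(joined["g"].to_numpy())
    fit = sm.OLS(y, X).fit()
    return {
        "trait": trait.name,
        "n": n,
        "beta": fit.params[1],
        "se": fit.bse[1],
        "p": fit.pvalues[1],
        "adj_r2": fit.rsquared_adj,
        "f": fit.fvalue,
    }


def instrument_validity(
    score: pd.Series, cohort, bmi_sd: pd.Series | None = None
) -> pd.DataFrame:
    """GRS association table for the exposure and each measured covariable.

    Rows: BMI in SD units (when supplied), BMI in kg/m^2, then age, sex,
    smoking and alcohol with their ordered-categorical numeric coding.
    Missing covariate values are dropped listwise per row.
    """
    traits: list[pd.Series] = []
    if bmi_sd is not None and len(bmi_sd):
        traits.append(bmi_sd.rename("bmi_sd"))
    traits.append(cohort.exposure.rename("bmi_kgm2"))
    for cov in ("age", "sex", "smoking", "alcohol"):
        traits.append(cohort.covariates[cov].rename(cov))
    rows = [_simple_ols_row(t, score) for t in traits]
    return pd.DataFrame(rows)


def shapiro_wilk(score) -> tuple[float, float]:
    """Shapiro-Wilk normality test of the score (Royston's algorithm)."""
    x = np.asarray(score, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk supported for 3 <= n <= 5000")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def grs_report(cohort, bmi_sd: pd.Series | None = None) -> GRSResult:
    """Convenience wrapper: score + validity table + normality check."""
    score = build_grs(cohort)
    validity = instrument_validity(score, cohort, bmi_sd=bmi_sd)
    n = len(score)
    normality = shapiro_wilk(score.sample(5000, random_state=0) if n > 5000 else score)
    return GRSResult(
        score=score, n_snps_used=cohort.n_snps, validity=validity, normality=normality
    )
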