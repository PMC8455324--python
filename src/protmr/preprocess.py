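"""Rank-based inverse-normal transformation and covariate pre-adjustment.

Protein traits are residualised on nuisance covariates by per-trait OLS and
the residuals mapped to normal quantiles of their ranks (residualise, then
transform — in that order).  The exposure is put on the same unitless SD
scale by the rank transform alone, so downstream effect estimates read as
SD protein per SD exposure.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class PreparedData:
    """Analysis-ready exposure and proteome.

    bmi_sd: exposure after the rank inverse-normal transform (SD units).
    proteome_adj: residualised + rank-inverse-normal protein z-scores.
    adjustment_spec: covariates regressed out of each protein.
    """

    bmi_sd: pd.Series
    proteome_adj: pd.DataFrame
    adjustment_spec: tuple[str, ...]


def rint(values, offset: str = "half") -> np.ndarray:
    """Rank inverse-normal transform.

    Maps values to ``Phi^-1((rank - c) / d)`` with average ranks for ties.
    ``offset='half'`` uses (rank - 0.5)/n (the GenABEL-style transform);
    ``offset='blom'`` uses (rank - 3/8)/(n + 1/4).  Strictly monotone in
    the input ranks; a constant vector has no rank information and raises.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("rint expects a 1-d vector")
    n = x.size
    if n < 3:
        raise ValueError("rint needs at least 3 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("rint input contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("rint input is constant")
    ranks = stats.rankdata(x, method="average")
    if offset == "half":
        q = (ranks - 0.5) / n
    elif offset == "blom":
        q = (ranks - 3.0 / 8.0) / (n + 0.25)
    else:
        raise ValueError(f"unknown rint offset {offset!r}")
    return stats.norm.ppf(q)


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return
    # identify offending columns: near-perfect fit on the remaining ones
    bad = []
    for j in range(design.shape[1]):
        others = np.delete(design, j, axis=1)
        coef, res, rk, _ = np.linalg.lstsq(others, design[:, j], rcond=None)
        fitted = others @ coef
        resid = design[:, j] - fitted
        denom = np.var(design[:, j])
        if denom == 0 or np.var(resid) / denom < 1e-10:
            bad.append(names[j])
    raise ValueError(f"collinear design columns: {bad or names}")


def residualize(matrix: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of ``matrix`` on ``design`` (with intercept)."""
    coef, *_ = np.linalg.lstsq(design, matrix, rcond=None)
    return matrix - design @ coef


def preadjust(
    proteome: pd.DataFrame,
    covariates: pd.DataFrame,
    exposure: pd.Series | None = None,
    covars: tuple[str, ...] = ("age", "sex"),
    offset: str = "half",
) -> PreparedData:
    """Residualise each protein on ``covars`` and rank-inverse-normalise.

    Rows with a missing value in any adjustment covariate are excluded
    (listwise).  When ``exposure`` is given it is rank-transformed on the
    same rows and returned as ``bmi_sd``; otherwise ``bmi_sd`` is empty.
    """
    sub = covariates[list(covars)].dropna()
    idx = proteome.index.intersection(sub.index)
    cov = sub.loc[idx].to_numpy(dtype=float)
    names = ["intercept"] + list(covars)
    design = np.column_stack([np.ones(len(idx)), cov])
    _check_full_rank(design, names)

    resid = residualize(proteome.loc[idx].to_numpy(dtype=float), design)
    adj = np.empty_like(resid)
    for j in range(resid.shape[1]):
        col = resid[:, j]
        if np.ptp(col) < 1e-12:
            # protein fully explained by covariates: residuals are numerical
            # noise; rank-transform of ties yields all-equal z of 0
            adj[:, j] = 0.0
        else:
            adj[:, j] = rint(col, offset=offset)
    proteome_adj = pd.DataFrame(adj, index=idx, columns=proteome.columns)

    if exposure is not None:
        bmi_sd = pd.Series(rint(exposure.loc[idx].to_numpy(), offset=offset), index=idx)
    else:
        bmi_sd = pd.Series(dtype=float)
    return PreparedData(bmi_sd=bmi_sd, proteome_adj=proteome_adj, adjustment_spec=tuple(covars))
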