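import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import protmr
from protmr.preprocess import PreparedData
from tests.conftest import make_truth


def _prepared_from_arrays(x, Y, ids=None):
    idx = pd.Index(ids or [f"i{i}" for i in range(len(x))], name="iid")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != len(x):
        Y = Y.T
    cols = [f"a{j}" for j in range(Y.shape[1])]
    return PreparedData(
        bmi_sd=pd.Series(np.asarray(x, dtype=float), index=idx),
        proteome_adj=pd.DataFrame(Y, index=idx, columns=cols),
        adjustment_spec=(),
    )


def _covars(n, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"i{i}" for i in range(n)], name="iid")
    return pd.DataFrame(
        {
            "age": rng.normal(45, 14, n),
            "sex": rng.choice([1.0, 2.0], n),
            "smoking": rng.choice([1.0, 2.0, 3.0], n),
            "alcohol": rng.choice([1.0, 2.0, 3.0, 4.0], n),
        },
        index=idx,
    )


def test_obs_scan_recovers_exact_linear_protein():
    rng = np.random.default_rng(1)
    n = 200
    x = rng.standard_normal(n)
    prep = _prepared_from_arrays(x, 0.7 * x)
    out = protmr.obs_scan(prep, _covars(n), model=1)
    assert abs(out["beta"].iloc[0] - 0.7) < 1e-8
    assert out["p"].iloc[0] < 1e-100


def test_obs_scan_matches_statsmodels_fit_per_protein():
    """The vectorised scan equals per-protein statsmodels OLS exactly."""
    rng = np.random.default_rng(2)
    n = 120
    x = rng.standard_normal(n)
    Y = rng.standard_normal((n, 5))
    cov = _covars(n, seed=3)
    prep = _prepared_from_arrays(x, Y)
    for model, covars in ((1, ["age", "sex"]), (2, ["age", "sex", "smoking", "alcohol"])):
        out = protmr.obs_scan(prep, cov, model=model)
        D = sm.add_constant(
            np.column_stack([x, cov[covars].to_numpy()])
        )
        for j in range(5):
            fit = sm.OLS(Y[:, j], D).fit()
            np.testing.assert_allclose(out["beta"].iloc[j], fit.params[1], rtol=1e-10)
            np.testing.assert_allclose(out["se"].iloc[j], fit.bse[1], rtol=1e-10)
            np.testing.assert_allclose(out["p"].iloc[j], fit.pvalues[1], rtol=1e-8)


def test_obs_scan_model2_uses_listwise_deletion():
    rng = np.random.default_rng(4)
    n = 150
    cov = _covars(n, seed=5)
    cov.loc[cov.index[:20], "alcohol"] = np.nan
    prep = _prepared_from_arrays(rng.standard_normal(n), rng.standard_normal((n, 3)))
    out1 = protmr.obs_scan(prep, cov, model=1)
    out2 = protmr.obs_scan(prep, cov, model=2)
    assert out1["n"].iloc[0] == n
    assert out2["n"].iloc[0] == n - 20


def test_covariable_scan_exact_effect():
    rng = np.random.default_rng(6)
    n = 400
    cov = _covars(n, seed=7)
    age_std = (cov["age"] - cov["age"].mean()) / cov["age"].std(ddof=0)
    prep = _prepared_from_arrays(rng.standard_normal(n), 0.3 * age_std.to_numpy())
    out = protmr.covariable_scan(prep, cov[["age"]])
    beta_per_year = out["beta"].iloc[0]
    assert abs(beta_per_year * cov["age"].std(ddof=0) - 0.3) < 1e-8


def test_identity_instrument_reduces_2sls_to_ols():
    """With instrument == exposure the IV estimate equals plain OLS."""
    rng = np.random.default_rng(8)
    n = 150
    x = rng.standard_normal(n)
    Y = 0.4 * x[:, None] + rng.standard_normal((n, 4))
    prep = _prepared_from_arrays(x, Y)
    mr, _ = protmr.mr_2sls(prep, prep.bmi_sd)
    D = sm.add_constant(x)
    for j in range(4):
        fit = sm.OLS(Y[:, j], D).fit()
        np.testing.assert_allclose(mr["beta"].iloc[j], fit.params[1], rtol=1e-10)


def test_2sls_equals_wald_ratio_on_printed_dataset():
    """n=8 worked example: IV estimate is the covariance ratio to 1e-12."""
    s = np.array([0.1, 0.4, 0.2, 0.9, 0.5, 0.3, 0.8, 0.6])
    x = np.array([1.2, 2.5, 0.8, 3.9, 2.2, 1.0, 3.1, 2.8])
    y = np.array([0.5, 1.8, 0.2, 2.9, 1.4, 0.9, 2.6, 1.7])
    prep = _prepared_from_arrays(x, y)
    score = pd.Series(s, index=prep.bmi_sd.index)
    mr, detail = protmr.mr_2sls(prep, score)
    sc = s - s.mean()
    wald = (sc @ y) / (sc @ x)  # cov(residualised GRS, y) / cov(..., x)
    assert abs(mr["beta"].iloc[0] - wald) < 1e-12
    r2 = np.corrcoef(s, x)[0, 1] ** 2
    np.testing.assert_allclose(
        detail["f_first_stage"].iloc[0], 6 * r2 / (1 - r2), rtol=1e-10
    )


@pytest.mark.parametrize("flavour", ["HC0", "HC1"])
def test_sandwich_se_matches_bruteforce(flavour):
    """Robust SEs equal the literal bread-meat-bread loop on random data."""
    rng = np.random.default_rng(9)
    for _ in range(20):
        n = int(rng.integers(25, 60))
        s = rng.standard_normal(n)
        x = 0.5 * s + rng.standard_normal(n)
        y = 0.7 * x + rng.standard_normal(n)
        prep = _prepared_from_arrays(x, y)
        score = pd.Series(s, index=prep.bmi_sd.index)
        mr, _ = protmr.mr_2sls(prep, score, robust=flavour)
        Z = np.column_stack([np.ones(n), s])
        X = np.column_stack([np.ones(n), x])
        A = np.linalg.inv(Z.T @ X)
        b = A @ Z.T @ y
        e = y - X @ b
        meat = sum(e[i] ** 2 * np.outer(Z[i], Z[i]) for i in range(n))
        V = A @ meat @ A.T
        if flavour == "HC1":
            V = V * n / (n - 2)
        assert abs(mr["se"].iloc[0] - np.sqrt(V[1, 1])) < 1e-10
        assert abs(mr["beta"].iloc[0] - b[1]) < 1e-12


def test_2sls_irrelevant_instrument_errors():
    rng = np.random.default_rng(10)
    n = 60
    prep = _prepared_from_arrays(rng.standard_normal(n), rng.standard_normal(n))
    with pytest.raises(ValueError, match="zero variance"):
        protmr.mr_2sls(prep, pd.Series(np.ones(n), index=prep.bmi_sd.index))


def test_confounded_null_protein_splits_obs_and_mr():
    """Confounding biases the observational slope but not the IV slope."""
    truth = make_truth(
        n_snps=20, causal_beta=[0.0], conf_load_x=0.5, conf_load_p=[0.5], seed=0
    )
    cohort = protmr.simulate_cohort(truth, n=20000, seed=5)
    prep = protmr.preadjust(cohort.proteome, cohort.covariates, exposure=cohort.exposure)
    score = protmr.build_grs(cohort)
    obs = protmr.obs_scan(prep, cohort.covariates, model=1)
    mr, _ = protmr.mr_2sls(prep, score)
    # closed-form omitted-variable slope: conf_x * conf_p / Var(X) = 0.25
    assert abs(obs["beta"].iloc[0] - 0.25) < 2 * obs["se"].iloc[0]
    assert obs["beta"].iloc[0] > 0.2
    assert abs(mr["beta"].iloc[0]) < 2 * mr["se"].iloc[0]


def test_mr_power_formula_properties():
    # beta -> 0 limit of the one-sided-NCP approximation is alpha / 2
    assert abs(protmr.mr_power(1000, 0.03, 0.0, 0.05) - 0.025) < 1e-12
    assert protmr.mr_power(2737, 0.028, 0.33, 0.05) >= 0.80
    # monotone in effect size and sample size
    assert protmr.mr_power(2737, 0.028, 0.5) > protmr.mr_power(2737, 0.028, 0.33)
    assert protmr.mr_power(5000, 0.028, 0.33) > protmr.mr_power(2737, 0.028, 0.33)
    with pytest.raises(ValueError):
        protmr.mr_power(100, 1.0, 0.3)
    with pytest.raises(ValueError):
        protmr.mr_power(100, 0.1, 0.3, alpha=0.0)


def test_agreement_identical_estimates_give_unit_slope():
    rng = np.random.default_rng(11)
    betas = rng.normal(size=30)
    obs = pd.DataFrame(
        {"aptamer": [f"a{i}" for i in range(30)], "beta": betas,
         "se": 0.1, "p": np.linspace(0.2, 0.9, 30)}
    )
    mr = obs.copy()
    res = protmr.agreement(obs, mr, threshold=0.05)
    alls = [r for r in res if r.subset == "all"][0]
    assert abs(alls.slope - 1.0) < 1e-10
    assert abs(alls.r2 - 1.0) < 1e-10
    assert alls.qq_obs is not None and len(alls.qq_obs) == 30


def test_agreement_requires_three_matched_proteins():
    df = pd.DataFrame({"aptamer": ["a", "b"], "beta": [1.0, 2.0], "se": 1, "p": 0.5})
    with pytest.raises(ValueError):
        protmr.agreement(df, df, threshold=0.05)
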