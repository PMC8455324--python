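import numpy as np
import pytest

import protmr
from protmr import simulate


def make_truth(
    n_snps=40,
    n_proteins=30,
    causal_beta=None,
    conf_load_x=0.0,
    conf_load_p=None,
    block_spec=None,
    target_r2=0.028,
    covariate_effects=None,
    missing_rates=None,
    seed=0,
):
    """Hand-assembled SimTruth with equal-weight SNPs (tests control all knobs)."""
    if causal_beta is None:
        causal_beta = np.zeros(n_proteins)
    causal_beta = np.asarray(causal_beta, dtype=float)
    n_proteins = len(causal_beta)
    if conf_load_p is None:
        conf_load_p = np.zeros(n_proteins)
    if block_spec is None:
        block_spec = [(1, 0.0)] * n_proteins
    truth = protmr.SimTruth(
        snp_mafs=np.full(n_snps, 0.3),
        weights=np.full(n_snps, 0.1),
        gamma=np.zeros(n_snps),
        causal_beta=causal_beta,
        conf_load_x=conf_load_x,
        conf_load_p=np.asarray(conf_load_p, dtype=float),
        block_spec=block_spec,
        target_r2_grs=target_r2,
        covariate_effects=covariate_effects if covariate_effects is not None else {},
        missing_rates=missing_rates if missing_rates is not None else {},
        seed=seed,
    )
    truth.gamma = simulate._calibrated_gamma(truth, truth.weights.copy())
    return truth


@pytest.fixture(scope="session")
def small_cohort():
    """Small mixed cohort: some causal proteins, confounding, blocks, missing covars."""
    rng = np.random.default_rng(7)
    P = 60
    causal = np.zeros(P)
    causal[:6] = [0.5, -0.4, 0.3, 0.25, -0.3, 0.2]
    conf_p = rng.normal(0, 0.15, P)
    blocks = [(5, 0.9)] * 2 + [(1, 0.0)] * (P - 10)
    truth = make_truth(
        n_snps=40,
        causal_beta=causal,
        conf_load_x=0.4,
        conf_load_p=conf_p,
        block_spec=blocks,
        covariate_effects=dict(simulate.DEFAULT_COVARIATE_EFFECTS),
        missing_rates=dict(simulate.DEFAULT_MISSING),
        seed=7,
    )
    cohort = protmr.simulate_cohort(truth, n=400, seed=17)
    return truth, cohort


@pytest.fixture(scope="session")
def small_prepared(small_cohort):
    _, cohort = small_cohort
    return protmr.preadjust(
        cohort.proteome, cohort.covariates, exposure=cohort.exposure
    )
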