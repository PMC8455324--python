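"""Observational and MR effect estimates on a confounded cohort.

A protein with no causal BMI effect but a shared confounder shows a biased
observational slope; the 2SLS estimate using the genetic score as the
instrument recovers the (null) causal effect.
"""

import numpy as np

import protmr

truth = protmr.SimTruth(
    snp_mafs=np.full(60, 0.3),
    weights=np.full(60, 0.1),
    gamma=np.zeros(60),
    causal_beta=np.array([0.0, 0.5]),  # null protein, causal protein
    conf_load_x=0.5,
    conf_load_p=np.array([0.5, 0.0]),
    block_spec=[(1, 0.0), (1, 0.0)],
    target_r2_grs=0.028,
    covariate_effects={},
    missing_rates={},
    seed=3,
)
from protmr.simulate import _calibrated_gamma

truth.gamma = _calibrated_gamma(truth, truth.weights.copy())
cohort = protmr.simulate_cohort(truth, n=20000, seed=3)
prepared = protmr.preadjust(cohort.proteome, cohort.covariates,
                            exposure=cohort.exposure)
score = protmr.build_grs(cohort)

obs = protmr.obs_scan(prepared, cohort.covariates, model=1)
mr, detail = protmr.mr_2sls(prepared, score)

for j, label in enumerate(["confounded null", "causal 0.5"]):
    print(f"{label:16s} obs beta {obs['beta'][j]:+.3f} (SE {obs['se'][j]:.3f})   "
          f"MR beta {mr['beta'][j]:+.3f} (SE {mr['se'][j]:.3f})")
print(f"first-stage F = {detail['f_first_stage'][0]:.1f}")
# The null protein's observational slope sits near the omitted-variable
# value 0.5*0.5 = 0.25 while its MR slope is ~0; the causal protein is
# recovered by both, MR with wider error bars.
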