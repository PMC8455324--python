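"""Run the whole analysis end to end on a simulated cohort.

Equivalent to `protmr run --seed 6 --outdir scratch/run6` from a shell;
here via the library so the report object can be inspected directly.
"""

from protmr import RunConfig, run_all

config = RunConfig(
    seed=6,
    sim_n=800,
    sim_n_snps=80,
    sim_n_proteins=150,
    kmeans_k_range=(2, 10),
)
report = run_all(config)

print(f"m_eff = {report.m_eff}, threshold = {report.threshold:.2e}")
print(f"hits: {report.hit_counts}")
print(f"chosen k = {report.chosen_k}, top cluster = {report.top_cluster}")
for a in report.agreement:
    print(f"agreement[{a.subset}]: slope {a.slope:.2f} (R^2 {a.r2:.2f}, n={a.n})")
# Observational hits exceed MR hits (confounding + instrument strength);
# the agreement slope near the obs-vs-MR relationship summarises how much
# of the observational signal the causal estimates track.
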