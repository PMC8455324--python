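"""End-to-end orchestration: simulate/read -> preprocess -> GRS -> scans ->
multiplicity -> clustering -> enrichment -> report.

A single master seed is forked deterministically per stage (SeedSequence
spawning), so e.g. changing the number of k-means restarts never perturbs
the simulation draws, and a rerun with the same config reproduces every
number bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations, cluster_enrich, grs, io, multiplicity, preprocess, simulate
from .datamodel import Cohort, RunConfig

log = logging.getLogger("protmr")


@dataclasses.dataclass
class RunReport:
    seed: int
    config: dict
    stage_n: dict
    grs_validity: pd.DataFrame
    grs_normality: tuple[float, float]
    m_eff: int
    threshold: float
    hit_counts: dict
    chosen_k: int
    cluster_effects_obs: pd.DataFrame
    cluster_effects_mr: pd.DataFrame
    top_cluster: int
    enrichment: pd.DataFrame
    agreement: list

    def to_json(self) -> str:
        # output paths are volatile run metadata, not analysis state
        config = {k: v for k, v in self.config.items() if k not in ("outdir", "paths")}
        payload = {
            "seed": self.seed,
            "config": config,
            "stage_n": self.stage_n,
            "grs_validity": self.grs_validity.to_dict(orient="records"),
            "grs_normality": {"W": self.grs_normality[0], "P": self.grs_normality[1]},
            "m_eff": self.m_eff,
            "threshold": self.threshold,
            "hit_counts": self.hit_counts,
            "chosen_k": self.chosen_k,
            "cluster_effects_obs": self.cluster_effects_obs.to_dict(orient="records"),
            "cluster_effects_mr": self.cluster_effects_mr.to_dict(orient="records"),
            "top_cluster": self.top_cluster,
            "enrichment": self.enrichment.to_dict(orient="records"),
            "agreement": [
                {
                    "subset": a.subset,
                    "slope": a.slope,
                    "se": a.se,
                    "r2": a.r2,
                    "p": a.p,
                    "n": a.n,
                }
                for a in self.agreement
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=float)


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_all(config: RunConfig, truth: simulate.SimTruth | None = None) -> RunReport:
    """Run every stage under one config; writes TSVs when outdir is set."""
    seed_sim, seed_kmeans, seed_annot, _ = _stage_seeds(config.seed)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- cohort ----------------------------------------------------------
    if config.paths:
        cohort = io.read_cohort(config.paths, config)
        if truth is None:
            log.info("cohort read from files; no ground truth available")
    else:
        if truth is None:
            truth = simulate.default_truth(
                n_snps=config.sim_n_snps,
                n_proteins=config.sim_n_proteins,
                target_r2_grs=config.sim_grs_r2,
                seed=seed_sim,
            )
        cohort = simulate.simulate_cohort(truth, n=config.sim_n, seed=seed_sim)
    log.info("stage=cohort n=%d snps=%d proteins=%d seed=%d",
             cohort.n, cohort.n_snps, cohort.n_proteins, config.seed)

    # --- preprocess ------------------------------------------------------
    prepared = preprocess.preadjust(
        cohort.proteome,
        cohort.covariates,
        exposure=cohort.exposure,
        covars=config.preadjust_covars,
        offset=config.rint_offset,
    )
    log.info("stage=preprocess n=%d", len(prepared.proteome_adj))

    # --- GRS -------------------------------------------------------------
    grs_res = grs.grs_report(cohort, bmi_sd=prepared.bmi_sd)
    log.info("stage=grs n=%d n_snps=%d", len(grs_res.score), grs_res.n_snps_used)

    # --- association scans ----------------------------------------------
    obs1 = associations.obs_scan(prepared, cohort.covariates, model=1)
    obs2 = associations.obs_scan(prepared, cohort.covariates, model=2)
    covar = associations.covariable_scan(prepared, cohort.covariates)
    mr, mr_detail = associations.mr_2sls(
        prepared, grs_res.score, robust=config.robust_se
    )
    log.info("stage=scans n_model1=%d n_model2=%d n_mr=%d",
             obs1["n"].iloc[0], obs2["n"].iloc[0], mr["n"].iloc[0])

    # --- multiplicity ----------------------------------------------------
    corr = multiplicity.spearman_matrix(prepared.proteome_adj)
    cut = multiplicity.count_independent(
        corr,
        cut_height=config.tree_cut_height,
        alpha_family=config.alpha_family,
        linkage_method=config.linkage_method,
    )
    log.info("stage=multiplicity m_eff=%d threshold=%.3e", cut.m_eff, cut.threshold)

    hit_counts = {
        "obs_model1": int((obs1["p"] < cut.threshold).sum()),
        "obs_model2": int((obs2["p"] < cut.threshold).sum()),
        "mr_2sls": int((mr["p"] < cut.threshold).sum()),
    }

    # --- clustering + effects -------------------------------------------
    pc_scores, explained, suggested = cluster_enrich.pca_proteins(
        prepared.proteome_adj, n_pcs=config.n_pcs
    )
    clustering = cluster_enrich.kmeans_scan(
        pc_scores,
        k_range=config.kmeans_k_range,
        seed=seed_kmeans,
        plateau_tol=config.plateau_tol,
    )
    clustering.explained_variance = explained
    eff_obs = cluster_enrich.cluster_effects(clustering.assignment, obs1)
    eff_mr = cluster_enrich.cluster_effects(clustering.assignment, mr)
    top = int(
        eff_mr.per_cluster.loc[
            eff_mr.per_cluster["median_abs_beta_se"].idxmax(), "cluster"
        ]
    )
    log.info("stage=cluster chosen_k=%d top_cluster=%d", clustering.chosen_k, top)

    # --- enrichment ------------------------------------------------------
    classes = ["cardiovascular", "renal", "cancer", "metabolic", "immune"]
    if truth is not None:
        enriched_set = list(
            cohort.proteome.columns[np.abs(truth.causal_beta) > 0]
        )
    else:  # no ground truth: seed annotations on the detected top cluster
        enriched_set = list(
            clustering.assignment.index[clustering.assignment == top]
        )
    annot = simulate.simulate_annotations(
        cohort.proteome.columns,
        enriched_set,
        classes,
        enrichment_fold=2.0,
        seed=seed_annot,
    )
    top_ids = clustering.assignment.index[clustering.assignment == top]
    try:
        enrichment = cluster_enrich.enrich(top_ids, annot)
    except ValueError as exc:  # e.g. a tiny top cluster with no annotations
        log.warning("enrichment skipped: %s", exc)
        enrichment = pd.DataFrame(
            columns=["class", "count", "list_total", "pop_hits", "pop_total",
                     "fold_enrichment", "ease_p", "bonferroni_p"]
        )

    # --- agreement -------------------------------------------------------
    agree = associations.agreement(obs1, mr, threshold=cut.threshold)

    report = RunReport(
        seed=config.seed,
        config=config.to_dict(),
        stage_n={
            "cohort": cohort.n,
            "obs_model1": int(obs1["n"].iloc[0]),
            "obs_model2": int(obs2["n"].iloc[0]),
            "mr": int(mr["n"].iloc[0]),
        },
        grs_validity=grs_res.validity,
        grs_normality=grs_res.normality,
        m_eff=cut.m_eff,
        threshold=cut.threshold,
        hit_counts=hit_counts,
        chosen_k=clustering.chosen_k,
        cluster_effects_obs=eff_obs.per_cluster,
        cluster_effects_mr=eff_mr.per_cluster,
        top_cluster=top,
        enrichment=enrichment,
        agreement=agree,
    )

    if outdir:
        io.write_table(obs1, outdir / "obs_model1.tsv")
        io.write_table(obs2, outdir / "obs_model2.tsv")
        io.write_table(covar, outdir / "covariable_scan.tsv")
        io.write_table(mr, outdir / "mr_2sls.tsv")
        io.write_table(mr_detail, outdir / "mr_detail.tsv")
        io.write_table(grs_res.validity, outdir / "grs_validity.tsv")
        io.write_table(
            cut.clusters.reset_index().rename(columns={"index": "aptamer"}),
            outdir / "meff_clusters.tsv",
        )
        io.write_table(clustering.k_scan, outdir / "kmeans_scan.tsv")
        io.write_table(
            clustering.assignment.reset_index().rename(columns={"index": "aptamer"}),
            outdir / "cluster_assignment.tsv",
        )
        if len(enrichment):
            io.write_table(enrichment, outdir / "enrichment.tsv")
        (outdir / "report.json").write_text(report.to_json())

    return report
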