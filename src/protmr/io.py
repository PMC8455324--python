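"""TSV readers/writers and cohort assembly.

All tabular interchange is TSV with a header row.  Floats are written at 10
significant digits so a write/read cycle is lossless at that precision.
Individual alignment across input files is by ID intersection; individuals
missing from any required block are dropped with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import Cohort, RunConfig

log = logging.getLogger("protmr")

ID_COLUMN = "iid"

COHORT_FILES = ("dosages", "snps", "covariates", "exposure", "proteome")


def write_table(rows: pd.DataFrame, path) -> Path:
    """Write a result table as TSV (header row, 10 s.f. floats)."""
    if rows is None or len(rows) == 0:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _read_indexed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if ID_COLUMN not in df.columns:
        raise ValueError(f"{path}: no {ID_COLUMN!r} column")
    if df[ID_COLUMN].duplicated().any():
        raise ValueError(f"{path}: duplicated individual IDs")
    return df.set_index(ID_COLUMN)


def read_cohort(paths: dict, config: RunConfig | None = None) -> Cohort:
    """Assemble a :class:`Cohort` from the five cohort TSVs.

    ``paths`` maps ``dosages``, ``snps``, ``covariates``, ``exposure``,
    ``proteome`` to file paths.  Rows are aligned on the intersection of
    individual IDs (keeping the dosage-file order); dropped individuals are
    counted in a warning.  Dosages outside [0, 2] raise, naming the SNP.
    """
    missing = [k for k in COHORT_FILES if k not in paths]
    if missing:
        raise ValueError(f"missing cohort input paths: {missing}")

    dosages = _read_indexed(paths["dosages"])
    covariates = _read_indexed(paths["covariates"])
    exposure_df = _read_indexed(paths["exposure"])
    proteome = _read_indexed(paths["proteome"])
    snp_meta = pd.read_csv(paths["snps"], sep="\t").set_index("snp_id")

    common = dosages.index
    for block in (covariates, exposure_df, proteome):
        common = common.intersection(block.index)
    common = dosages.index[dosages.index.isin(common)]  # keep dosage order
    n_dropped = sum(
        len(block.index.difference(common))
        for block in (dosages, covariates, exposure_df, proteome)
    )
    if len(common) == 0:
        raise ValueError("no individuals shared across all cohort files")
    if n_dropped:
        log.warning(
            "read_cohort: dropped %d individual rows not present in every block; "
            "N=%d retained", n_dropped, len(common)
        )

    if "bmi" not in exposure_df.columns:
        raise ValueError("exposure file must have a 'bmi' column")

    return Cohort(
        dosages=dosages.loc[common],
        snp_meta=snp_meta,
        covariates=covariates.loc[common],
        exposure=exposure_df.loc[common, "bmi"],
        proteome=proteome.loc[common],
    )


def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write the five cohort TSVs under ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{k}.tsv" for k in COHORT_FILES}
    write_table(cohort.dosages.rename_axis(ID_COLUMN).reset_index(), paths["dosages"])
    write_table(cohort.snp_meta.rename_axis("snp_id").reset_index(), paths["snps"])
    write_table(
        cohort.covariates.rename_axis(ID_COLUMN).reset_index(), paths["covariates"]
    )
    write_table(
        cohort.exposure.rename("bmi").rename_axis(ID_COLUMN).reset_index(),
        paths["exposure"],
    )
    write_table(cohort.proteome.rename_axis(ID_COLUMN).reset_index(), paths["proteome"])
    return {k: str(v) for k, v in paths.items()}
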