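"""Core data containers shared by every stage of the analysis.

The analysis works on a *cohort*: a set of individuals with effect-allele
dosages at instrument SNPs, a continuous exposure (BMI), a small covariate
table, and a wide protein-abundance matrix.  All blocks are row-aligned on
individual IDs; alignment is by ID intersection, never positional, because
per-analysis sample sizes differ (listwise deletion happens downstream,
per model).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

REQUIRED_COVARIATES = ("age", "sex", "smoking", "alcohol")

#: Covariate coding used throughout: sex 1=female, 2=male; smoking 1=never,
#: 2=occasional, 3=most days or every day; alcohol 1=rarely, 2=<1/week,
#: 3=1-2/week, 4=3-5/week or most days.
COVARIATE_CODING = {
    "sex": (1, 2),
    "smoking": (1, 3),
    "alcohol": (1, 4),
}


@dataclasses.dataclass
class Cohort:
    """Row-aligned cohort data.

    Attributes
    ----------
    dosages : DataFrame, individuals x SNPs
        Effect-allele dosages in [0, 2].
    snp_meta : DataFrame indexed by SNP id
        Columns ``effect_allele``, ``other_allele``, ``weight`` (per-allele
        effect estimate from the source GWAS of the exposure).
    covariates : DataFrame, individuals x covariates
        At least age (years), sex, smoking, alcohol; NaN marks a missing
        covariate value (handled by listwise deletion per model).
    exposure : Series
        BMI in kg/m^2.
    proteome : DataFrame, individuals x aptamers
        Protein abundances (RFU-like or already on a z-score scale); no
        missing values are permitted.
    protein_names : optional mapping aptamer id -> protein name.
    """

    dosages: pd.DataFrame
    snp_meta: pd.DataFrame
    covariates: pd.DataFrame
    exposure: pd.Series
    proteome: pd.DataFrame
    protein_names: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        ids = self.dosages.index
        if len(ids) == 0:
            raise ValueError("cohort has no individuals")
        if self.dosages.shape[1] == 0:
            raise ValueError("cohort has no SNPs")
        if self.proteome.shape[1] == 0:
            raise ValueError("cohort has no proteins")
        for name, block in (
            ("covariates", self.covariates),
            ("exposure", self.exposure),
            ("proteome", self.proteome),
        ):
            if not block.index.equals(ids):
                raise ValueError(f"{name} block is not row-aligned with dosages")
        missing = self.snp_meta.index.symmetric_difference(self.dosages.columns)
        if len(missing):
            raise ValueError(f"snp_meta does not cover dosage SNPs: {list(missing)[:5]}")
        vals = self.dosages.to_numpy()
        bad = (vals < 0) | (vals > 2) | ~np.isfinite(vals)
        if bad.any():
            j = int(np.argwhere(bad.any(axis=0)).ravel()[0])
            raise ValueError(
                f"dosage outside [0, 2] for SNP {self.dosages.columns[j]!r}"
            )
        if self.proteome.isna().to_numpy().any():
            raise ValueError("proteome contains missing values")
        for cov in REQUIRED_COVARIATES:
            if cov not in self.covariates.columns:
                raise ValueError(f"required covariate {cov!r} absent")

    # -- convenience ------------------------------------------------------
    @property
    def ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def n(self) -> int:
        return len(self.dosages)

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_proteins(self) -> int:
        return self.proteome.shape[1]

    def subset(self, ids: Sequence) -> "Cohort":
        """Return the cohort restricted to ``ids`` (order preserved)."""
        idx = pd.Index(ids)
        return Cohort(
            dosages=self.dosages.loc[idx],
            snp_meta=self.snp_meta,
            covariates=self.covariates.loc[idx],
            exposure=self.exposure.loc[idx],
            proteome=self.proteome.loc[idx],
            protein_names=self.protein_names,
        )


@dataclasses.dataclass
class RunConfig:
    """Run-level configuration with the analysis defaults.

    ``alpha_family`` and ``tree_cut_height`` drive the multiplicity
    correction (family-wise 0.05 split over the effective number of
    independent proteins found by cutting the correlation dendrogram at
    height 0.2, i.e. |r| >= 0.8 collapses traits).
    """

    alpha_family: float = 0.05
    tree_cut_height: float = 0.2
    kmeans_k_range: tuple[int, int] = (2, 20)
    n_pcs: int | str = "auto"
    seed: int = 0
    robust_se: str = "HC1"
    rint_offset: str = "half"
    preadjust_covars: tuple[str, ...] = ("age", "sex")
    plateau_tol: float = 0.01
    linkage_method: str = "complete"
    # simulation block (used when no input files are given)
    sim_n: int = 2737
    sim_n_snps: int = 654
    sim_n_proteins: int = 4034
    sim_grs_r2: float = 0.028
    # file paths; when set, read_cohort is used instead of the simulator
    paths: dict | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha_family < 1:
            raise ValueError("alpha_family must be in (0, 1)")
        if not 0 < self.tree_cut_height < 2:
            raise ValueError("tree_cut_height must be in (0, 2)")
        lo, hi = self.kmeans_k_range
        if lo < 2 or hi < lo:
            raise ValueError("kmeans_k_range must satisfy 2 <= lo <= hi")
        if self.robust_se not in ("HC0", "HC1"):
            raise ValueError("robust_se must be HC0 or HC1")
        if self.rint_offset not in ("half", "blom"):
            raise ValueError("rint_offset must be 'half' or 'blom'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "kmeans_k_range" in raw:
            raw["kmeans_k_range"] = tuple(raw["kmeans_k_range"])
        if "preadjust_covars" in raw:
            raw["preadjust_covars"] = tuple(raw["preadjust_covars"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kmeans_k_range"] = list(self.kmeans_k_range)
        d["preadjust_covars"] = list(self.preadjust_covars)
        return d


@dataclasses.dataclass
class AnnotationTable:
    """Protein -> disease-class annotation against a fixed background.

    ``mapping`` holds, for every annotated protein id, its set of
    disease-class labels; ``background`` is the full measured protein list
    (the enrichment population).  Every annotated id must be in the
    background and labels must be non-empty strings.
    """

    mapping: dict[str, frozenset[str]]
    background: tuple[str, ...]

    def __post_init__(self) -> None:
        bg = set(self.background)
        for pid, classes in self.mapping.items():
            if pid not in bg:
                raise ValueError(f"annotated id {pid!r} not in background")
            for c in classes:
                if not isinstance(c, str) or not c:
                    raise ValueError(f"empty class label for {pid!r}")

    @property
    def classes(self) -> list[str]:
        out: set[str] = set()
        for cs in self.mapping.values():
            out |= cs
        return sorted(out)

    def ids_in_class(self, label: str) -> set[str]:
        return {pid for pid, cs in self.mapping.items() if label in cs}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein_id": pid, "class": c}
            for pid, cs in sorted(self.mapping.items())
            for c in sorted(cs)
        ]
        return pd.DataFrame(rows, columns=["protein_id", "class"])
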