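"""Arsenic-metabolite phenotype definitions and phenotype/covariate tables.

Urinary arsenic species (inorganic As, MMA, DMA) are expressed as
percentages of their sum; arsenobetaine and arsenocholine — non-toxic
dietary organic arsenic — are excluded from the denominator.  DMA% is the
methylation-efficiency phenotype used throughout the analyses.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

#: covariate columns expected by the model-fitting layer, with their codings
COVARIATE_COLUMNS = {
    "age": "years, continuous",
    "sex": "0 = male, 1 = female",
    "batch": "genotyping batch, 0/1",
    "water_as_quartile": "water arsenic quartile, 1-4",
    "smoking": "0 never, 1 former, 2 current",
    "bmi_cat": "ordered BMI category, 0/1/2",
}

CATEGORICAL_COVARIATES = ("water_as_quartile", "smoking", "bmi_cat")


@dataclasses.dataclass
class PhenotypeTable:
    """Per-sample phenotype and covariates, keyed by sample_id.

    The underlying DataFrame must contain ``sample_id`` and ``dma_pct``;
    ``mma_pct``/``ias_pct`` and the covariate columns are optional but
    validated when present.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.df.columns or "dma_pct" not in self.df.columns:
            raise ValueError("PhenotypeTable needs sample_id and dma_pct columns")
        if self.df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in phenotype table")
        if {"mma_pct", "ias_pct"} <= set(self.df.columns):
            total = self.df[["dma_pct", "mma_pct", "ias_pct"]].sum(axis=1)
            complete = total.notna()
            if complete.any() and not np.allclose(total[complete], 100.0, atol=1e-9):
                raise ValueError("species percentages must sum to 100")

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def aligned_to(self, sample_ids) -> "PhenotypeTable":
        """Reorder/subset rows to match an external sample ordering."""
        indexed = self.df.set_index("sample_id")
        missing = [s for s in sample_ids if s not in indexed.index]
        if missing:
            raise KeyError(f"phenotype table lacks samples: {missing[:5]}")
        return PhenotypeTable(indexed.loc[list(sample_ids)].reset_index())

    def covariate_design(self, columns=None) -> np.ndarray:
        """Fixed-effect design matrix: intercept + covariates.

        Categorical covariates are expanded to indicator columns (first
        level as reference); continuous/binary columns enter as-is.
        """
        if columns is None:
            columns = [c for c in COVARIATE_COLUMNS if c in self.df.columns]
        blocks = [np.ones((len(self.df), 1))]
        for col in columns:
            v = self.df[col].to_numpy()
            if col in CATEGORICAL_COVARIATES:
                levels = np.unique(v)
                for lev in levels[1:]:
                    blocks.append((v == lev).astype(float)[:, None])
            else:
                blocks.append(v.astype(float)[:, None])
        return np.hstack(blocks)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t"))


def metabolite_percentages(ias, mma, dma, asb=0.0, asc=0.0):
    """Species percentages of summed toxic urinary arsenic.

    Arsenobetaine/arsenocholine are excluded from the denominator by
    construction.  Inputs are concentrations (ug/L); scalars or arrays.
    Returns (ias_pct, mma_pct, dma_pct).
    """
    ias, mma, dma = (np.asarray(v, dtype=float) for v in (ias, mma, dma))
    if (ias < 0).any() or (mma < 0).any() or (dma < 0).any():
        raise ValueError("species concentrations must be non-negative")
    denom = ias + mma + dma
    if np.any(denom <= 0):
        raise ValueError("sum of toxic arsenic species must be positive")
    return tuple(100.0 * v / denom for v in (ias, mma, dma))


def creatinine_adjust(total_as, creatinine):
    """Creatinine-adjusted total urinary arsenic (ug per g creatinine)."""
    total_as = np.asarray(total_as, dtype=float)
    creatinine = np.asarray(creatinine, dtype=float)
    if np.any(creatinine <= 0):
        raise ValueError("creatinine must be positive")
    return total_as / creatinine
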