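"""Phenotype/covariate tables and GWAS summary statistics containers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ParameterError

SUMMARY_COLUMNS = ["variant_id", "effect_allele", "other_allele", "beta", "se", "p", "n"]


@dataclass
class PhenotypeTable:
    """Trait values plus covariates over a cohort's samples."""

    sample_ids: list[str]
    trait_name: str
    trait_type: str  # "binary" | "quantitative"
    values: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ParameterError(f"unknown trait_type {self.trait_type!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids),):
            raise AlignmentError("trait values do not align with sample_ids")
        if self.trait_type == "binary":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ParameterError("binary trait values must be 0/1")
        if len(self.covariates) not in (0, len(self.sample_ids)):
            raise AlignmentError("covariate rows do not align with sample_ids")
        if len(self.covariates):
            self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def covariate_matrix(self) -> np.ndarray:
        """Covariates as a float matrix (n x k; k may be 0)."""
        if not len(self.covariates):
            return np.zeros((self.n, 0))
        return self.covariates.to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"sample_id": self.sample_ids, self.trait_name: self.values})
        for c in self.covariates.columns:
            df[c] = self.covariates[c].to_numpy()
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(
        cls, path: str | Path, trait_name: str, trait_type: str
    ) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t")
        cov_cols = [c for c in df.columns if c not in ("sample_id", trait_name)]
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            trait_name=trait_name,
            trait_type=trait_type,
            values=df[trait_name].to_numpy(dtype=float),
            covariates=df[cov_cols].copy(),
        )


@dataclass
class SummaryStats:
    """Per-variant GWAS summary statistics.

    ``table`` columns: variant_id, effect_allele, other_allele, beta, se,
    p, n. Effects are on the per-effect-allele dosage scale.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMMARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ParameterError(f"summary table missing columns: {missing}")
        self.table = self.table[SUMMARY_COLUMNS].reset_index(drop=True)
        if (self.table["se"].to_numpy() <= 0).any():
            raise ParameterError("all standard errors must be positive")
        p = self.table["p"].to_numpy()
        if ((p <= 0) | (p > 1)).any():
            raise ParameterError("p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("variant_id")

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.rename(
            columns={
                "effect_allele": "A1",
                "other_allele": "A2",
                "beta": "BETA",
                "se": "SE",
                "p": "P",
                "n": "N",
            }
        )
        out.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SummaryStats":
        df = pd.read_csv(path, sep="\t")
        df = df.rename(
            columns={
                "A1": "effect_allele",
                "A2": "other_allele",
                "BETA": "beta",
                "SE": "se",
                "P": "p",
                "N": "n",
            }
        )
        return cls(df)
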