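"""Genotype dosage panels and their on-disk formats.

The in-memory container is a samples x variants dosage matrix (values in
[0, 2] counting effect alleles) plus a variant table. Two text formats are
supported: the dosage TSV layout used by individual-level TWAS tools
(chrom, variant_id, pos, ref, effect, MAF, then one dosage column per
sample) and VCF with a ``DS`` FORMAT field (via pysam).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ParameterError

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref_allele", "effect_allele", "maf"]


@dataclass
class GenotypePanel:
    """Dosage matrix over samples x variants.

    ``variants`` has columns variant_id, chrom, pos (1-based), ref_allele,
    effect_allele, maf; ``dosages`` is float32, shape
    ``(len(sample_ids), len(variants))`` with entries in [0, 2].
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ParameterError(f"variant table missing columns: {missing}")
        self.variants = self.variants[VARIANT_COLUMNS].reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise AlignmentError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if self.variants["variant_id"].duplicated().any():
            raise ParameterError("variant ids must be unique")
        maf = self.variants["maf"].to_numpy()
        if ((maf <= 0) | (maf > 0.5)).any():
            raise ParameterError("maf must lie in (0, 0.5]")
        if np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2:
            raise ParameterError("dosages must lie in [0, 2]")
        for _, sub in self.variants.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ParameterError("positions must be non-decreasing within chrom")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> pd.Index:
        """Cached variant_id -> column position index."""
        idx = getattr(self, "_vindex", None)
        if idx is None:
            idx = pd.Index(self.variants["variant_id"])
            object.__setattr__(self, "_vindex", idx)
        return idx

    def variant_positions(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Column positions of ``variant_ids`` (-1 where absent)."""
        return self.variant_index().get_indexer(list(variant_ids))

    def allele_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached (effect_allele, ref_allele) arrays for fast harmonization."""
        arrs = getattr(self, "_alleles", None)
        if arrs is None:
            arrs = (
                self.variants["effect_allele"].to_numpy(),
                self.variants["ref_allele"].to_numpy(),
            )
            object.__setattr__(self, "_alleles", arrs)
        return arrs

    def dosage_frame(self, variant_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Samples x variants dosage DataFrame (float64), optionally subset."""
        if variant_ids is None:
            cols = self.variants["variant_id"]
            data = self.dosages.astype(float)
        else:
            pos = self.variant_positions(variant_ids)
            if (pos < 0).any():
                missing = [v for v, p in zip(variant_ids, pos) if p < 0]
                raise AlignmentError(f"variants absent from panel: {missing[:5]}")
            cols = list(variant_ids)
            data = self.dosages[:, pos].astype(float)
        return pd.DataFrame(data, index=self.sample_ids, columns=cols)

    def cis_variant_ids(
        self, chrom: str, start: int, end: int, window_bp: int
    ) -> list[str]:
        """Variants within [start - window, end + window) on ``chrom``."""
        v = self.variants
        mask = (
            (v["chrom"] == chrom)
            & (v["pos"] >= start - window_bp)
            & (v["pos"] < end + window_bp)
        )
        return v.loc[mask, "variant_id"].tolist()

    # ------------------------------------------------------------------ io
    def to_dosage_tsv(self, path: str | Path) -> None:
        header = ["chrom", "variant_id", "pos", "ref_allele", "effect_allele", "maf"]
        out = self.variants[["chrom", "variant_id", "pos", "ref_allele", "effect_allele", "maf"]].copy()
        dos = pd.DataFrame(
            self.dosages.T, columns=self.sample_ids, index=out.index
        )
        pd.concat([out, dos], axis=1).to_csv(
            path, sep="\t", index=False, float_format="%.6g", header=header + list(self.sample_ids)
        )

    @classmethod
    def from_dosage_tsv(cls, path: str | Path) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t")
        meta_cols = ["chrom", "variant_id", "pos", "ref_allele", "effect_allele", "maf"]
        sample_ids = [c for c in df.columns if c not in meta_cols]
        variants = df[meta_cols].rename(columns={})[
            ["variant_id", "chrom", "pos", "ref_allele", "effect_allele", "maf"]
        ]
        dosages = df[sample_ids].to_numpy(dtype=np.float32).T
        return cls(sample_ids=sample_ids, variants=variants, dosages=dosages)

    def to_vcf(self, path: str | Path) -> None:
        """Write an uncompressed VCF with a DS (dosage) FORMAT field."""
        import pysam

        header = pysam.VariantHeader()
        header.add_meta("source", "cnvpairtwas")
        for chrom in dict.fromkeys(self.variants["chrom"]):
            # synthetic contigs: length just needs to exceed the last position
            max_pos = int(self.variants.loc[self.variants["chrom"] == chrom, "pos"].max())
            header.contigs.add(str(chrom), length=max_pos + 1)
        header.formats.add("DS", 1, "Float", "Estimated alternate allele dosage")
        for s in self.sample_ids:
            header.add_sample(s)
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for j, row in enumerate(self.variants.itertuples(index=False)):
                rec = vcf.new_record(
                    contig=str(row.chrom),
                    start=int(row.pos) - 1,
                    stop=int(row.pos),
                    alleles=(row.ref_allele, row.effect_allele),
                    id=row.variant_id,
                )
                for i, s in enumerate(self.sample_ids):
                    rec.samples[s]["DS"] = float(self.dosages[i, j])
                vcf.write(rec)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypePanel":
        """Read a VCF with DS FORMAT into a panel (MAF recomputed from DS)."""
        import pysam

        rows = []
        dosage_cols = []
        sample_ids: list[str] = []
        with pysam.VariantFile(str(path)) as vcf:
            sample_ids = list(vcf.header.samples)
            for rec in vcf:
                ds = np.array(
                    [float(rec.samples[s]["DS"]) for s in sample_ids], dtype=np.float32
                )
                freq = float(ds.mean() / 2.0)
                maf = min(freq, 1.0 - freq)
                rows.append(
                    (
                        rec.id,
                        rec.contig,
                        rec.pos,
                        rec.alleles[0],
                        rec.alleles[1],
                        maf if maf > 0 else 1e-6,
                    )
                )
                dosage_cols.append(ds)
        variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
        dosages = np.column_stack(dosage_cols) if dosage_cols else np.zeros((len(sample_ids), 0), np.float32)
        return cls(sample_ids=sample_ids, variants=variants, dosages=dosages)
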