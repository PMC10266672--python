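"""Gene catalogs and CNV region definitions.

Coordinates follow the 0-based half-open convention (BED-like). A CNV
region is a contiguous genomic interval plus the list of member genes that
fall inside it (flanking genes within ``flank_bp`` may also be members,
mirroring the common practice of analysing genes within 200 kb of
recurrent CNV breakpoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import CatalogError, ParameterError

BIOTYPES = ("protein_coding", "lincRNA", "pseudogene", "antisense", "miRNA")
#: biotypes counted as coding; everything else is noncoding
CODING_BIOTYPES = frozenset({"protein_coding"})

CATALOG_COLUMNS = ["gene_id", "chrom", "start", "end", "biotype"]


def is_coding(biotype: str) -> bool:
    return biotype in CODING_BIOTYPES


@dataclass
class GeneCatalog:
    """A table of genes with coordinates and biotypes.

    ``genes`` holds columns gene_id, chrom, start, end, biotype, sorted by
    (chrom, start). Invariants (unique ids, start < end, known biotypes)
    are checked on construction.
    """

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.genes
        missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
        if missing:
            raise ParameterError(f"catalog is missing columns: {missing}")
        df = df[CATALOG_COLUMNS].copy()
        if df["gene_id"].duplicated().any():
            dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ParameterError(f"duplicate gene ids: {dups[:5]}")
        if (df["start"] >= df["end"]).any():
            raise ParameterError("every gene must satisfy start < end")
        bad = set(df["biotype"]) - set(BIOTYPES)
        if bad:
            raise ParameterError(f"unknown biotypes: {sorted(bad)}")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        df["coding"] = df["biotype"].map(is_coding)
        object.__setattr__(self, "genes", df)

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> pd.Series:
        rows = self.genes.index[self.genes["gene_id"] == gene_id]
        if len(rows) == 0:
            raise CatalogError(gene_id)
        return self.genes.loc[rows[0]]

    def subset(self, gene_ids: Iterable[str]) -> "GeneCatalog":
        wanted = set(gene_ids)
        unknown = wanted - set(self.genes["gene_id"])
        if unknown:
            raise CatalogError(sorted(unknown)[0])
        return GeneCatalog(self.genes[self.genes["gene_id"].isin(wanted)].copy())

    # ------------------------------------------------------------------ io
    def to_tsv(self, path: str | Path) -> None:
        """BED-like TSV: chrom, start, end, gene_id, biotype."""
        out = self.genes[["chrom", "start", "end", "gene_id", "biotype"]]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCatalog":
        df = pd.read_csv(path, sep="\t")
        return cls(df[["gene_id", "chrom", "start", "end", "biotype"]])


@dataclass
class RegionDefinition:
    """A named genomic interval with explicit member genes."""

    region_id: str
    chrom: str
    start: int
    end: int
    member_gene_ids: list[str] = field(default_factory=list)
    flank_bp: int = 200_000

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParameterError(
                f"region {self.region_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if not self.member_gene_ids:
            raise ParameterError(f"region {self.region_id}: member gene list is empty")
        if self.flank_bp < 0:
            raise ParameterError("flank_bp must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and start < self.end and self.start < end

    def validate_members(self, catalog: GeneCatalog) -> None:
        """Check every member lies within [start - flank, end + flank)."""
        lo, hi = self.start - self.flank_bp, self.end + self.flank_bp
        for gid in self.member_gene_ids:
            g = catalog.gene(gid)
            if g["chrom"] != self.chrom or g["start"] < lo or g["start"] >= hi:
                raise ParameterError(
                    f"gene {gid} lies outside region {self.region_id} (+/- flank)"
                )

    def coding_noncoding_counts(self, catalog: GeneCatalog) -> tuple[int, int]:
        sub = catalog.subset(self.member_gene_ids).genes
        coding = int(sub["coding"].sum())
        return coding, len(sub) - coding


def write_regions_tsv(
    regions: Sequence[RegionDefinition],
    regions_path: str | Path,
    membership_path: str | Path,
) -> None:
    """Write regions as BED-like TSV plus a (region_id, gene_id) membership TSV."""
    reg = pd.DataFrame(
        [(r.region_id, r.chrom, r.start, r.end, r.flank_bp) for r in regions],
        columns=["region_id", "chrom", "start", "end", "flank_bp"],
    )
    mem = pd.DataFrame(
        [(r.region_id, g) for r in regions for g in r.member_gene_ids],
        columns=["region_id", "gene_id"],
    )
    reg.to_csv(regions_path, sep="\t", index=False)
    mem.to_csv(membership_path, sep="\t", index=False)


def read_regions_tsv(
    regions_path: str | Path, membership_path: str | Path
) -> list[RegionDefinition]:
    reg = pd.read_csv(regions_path, sep="\t")
    mem = pd.read_csv(membership_path, sep="\t")
    grouped = mem.groupby("region_id")["gene_id"].apply(list)
    out = []
    for row in reg.itertuples(index=False):
        out.append(
            RegionDefinition(
                region_id=row.region_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                member_gene_ids=list(grouped.get(row.region_id, [])),
                flank_bp=int(row.flank_bp),
            )
        )
    return out
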