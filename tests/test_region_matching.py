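"""Control-region selection vs an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

import cnvpairtwas as ct
from cnvpairtwas.catalog import GeneCatalog, RegionDefinition
from cnvpairtwas.region_matching import match_control_regions


def brute_force_controls(target, catalog, length_bounds=(0.8, 1.2),
                         ratio_min_fraction=0.8, exclusions=()):
    """Naive re-implementation: enumerate every window, filter the three
    criteria, then greedy left-to-right non-overlap."""
    m = len(target.member_gene_ids)
    t_sub = catalog.subset(target.member_gene_ids).genes
    t_coding = int(t_sub["coding"].sum())
    t_noncoding = m - t_coding
    t_len = target.length
    out = []
    for chrom in sorted(catalog.genes["chrom"].unique()):
        sub = catalog.genes[catalog.genes["chrom"] == chrom].sort_values("start")
        rows = list(sub.itertuples(index=False))
        prev_end = None
        for i in range(len(rows) - m + 1):
            win = rows[i : i + m]
            start, end = win[0].start, win[-1].end
            length = end - start
            if not (length_bounds[0] * t_len <= length <= length_bounds[1] * t_len):
                continue
            coding = sum(1 for g in win if g.biotype == "protein_coding")
            noncoding = m - coding
            if t_noncoding == 0:
                if noncoding != 0:
                    continue
            elif noncoding > 0 and coding / noncoding < ratio_min_fraction * (
                t_coding / t_noncoding
            ):
                continue
            interval_hits = lambda r: r.chrom == chrom and start < r.end and r.start < end
            if interval_hits(target) or any(interval_hits(e) for e in exclusions):
                continue
            if prev_end is not None and start < prev_end:
                continue
            out.append(tuple(g.gene_id for g in win))
            prev_end = end
    return out


def _random_catalog(seed, n_genes=60):
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in ("chr1", "chr2"):
        pos = 1000
        for i in range(n_genes // 2):
            start = pos + int(rng.integers(0, 30_000))
            length = int(rng.integers(5_000, 60_000))
            bt = rng.choice(["protein_coding", "lincRNA", "pseudogene"], p=[0.7, 0.2, 0.1])
            rows.append((f"{chrom}_g{i}", chrom, start, start + length, bt))
            pos = start + length + int(rng.integers(1_000, 40_000))
    return GeneCatalog(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "biotype"]))


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
def test_matches_brute_force_oracle_on_random_catalogs(seed):
    catalog = _random_catalog(seed)
    genes = catalog.genes
    # target: a 4-gene window on chr1
    window = genes[genes["chrom"] == "chr1"].iloc[3:7]
    target = RegionDefinition(
        region_id="T",
        chrom="chr1",
        start=int(window["start"].iloc[0]),
        end=int(window["end"].iloc[-1]),
        member_gene_ids=window["gene_id"].tolist(),
    )
    got = match_control_regions(target, catalog)
    expected = brute_force_controls(target, catalog)
    assert [tuple(r.member_gene_ids) for r in got] == expected
    # the target window itself is never returned
    assert all(tuple(r.member_gene_ids) != tuple(target.member_gene_ids) for r in got)
    # accepted windows are mutually non-overlapping
    for a, b in zip(got, got[1:]):
        assert a.chrom != b.chrom or a.end <= b.start


def _toy_catalog_with_spans(spans):
    """Catalog with 3-gene windows of controlled span on separate chroms."""
    rows = [
        ("t1", "chrT", 0, 40_000, "protein_coding"),
        ("t2", "chrT", 45_000, 70_000, "protein_coding"),
        ("t3", "chrT", 80_000, 100_000, "protein_coding"),
    ]
    for j, span in enumerate(spans):
        chrom = f"chr{j}"
        rows += [
            (f"c{j}a", chrom, 0, span // 3, "protein_coding"),
            (f"c{j}b", chrom, span // 2, 2 * span // 3, "protein_coding"),
            (f"c{j}c", chrom, 3 * span // 4, span, "protein_coding"),
        ]
    return GeneCatalog(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "biotype"]))


def test_length_bounds_are_inclusive():
    catalog = _toy_catalog_with_spans([80_000, 79_000, 120_000, 121_000])
    target = RegionDefinition(
        region_id="T", chrom="chrT", start=0, end=100_000,
        member_gene_ids=["t1", "t2", "t3"],
    )
    got = {tuple(r.member_gene_ids) for r in match_control_regions(target, catalog)}
    assert ("c0a", "c0b", "c0c") in got  # exactly 0.8 x target length
    assert ("c1a", "c1b", "c1c") not in got  # 0.79 x
    assert ("c2a", "c2b", "c2c") in got  # exactly 1.2 x
    assert ("c3a", "c3b", "c3c") not in got  # 1.21 x


def test_zero_noncoding_target_requires_zero_noncoding_candidates():
    rows = [
        ("t1", "chrT", 0, 40_000, "protein_coding"),
        ("t2", "chrT", 50_000, 100_000, "protein_coding"),
        ("a1", "chr1", 0, 40_000, "protein_coding"),
        ("a2", "chr1", 50_000, 100_000, "protein_coding"),
        ("b1", "chr2", 0, 40_000, "protein_coding"),
        ("b2", "chr2", 50_000, 100_000, "miRNA"),
    ]
    catalog = GeneCatalog(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "biotype"]))
    target = RegionDefinition(
        region_id="T", chrom="chrT", start=0, end=100_000, member_gene_ids=["t1", "t2"]
    )
    got = {tuple(r.member_gene_ids) for r in match_control_regions(target, catalog)}
    assert got == {("a1", "a2")}


def test_exclusion_regions_are_respected(universe):
    catalog, region = universe["catalog"], universe["region"]
    unrestricted = match_control_regions(region, catalog)
    assert unrestricted  # sanity: demo catalog yields controls
    first = unrestricted[0]
    excl = RegionDefinition(
        region_id="EX", chrom=first.chrom, start=first.start, end=first.end,
        member_gene_ids=["_"],
    )
    restricted = match_control_regions(region, catalog, exclusions=[excl])
    assert all(
        not r.overlaps(excl.chrom, excl.start, excl.end) for r in restricted
    )
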