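"""Which genes drive significant pairs: membership counts and
over-representation flags.

A gene that appears in significant pairs far more often than its region
peers (count above mean + k SD of all region genes' counts) is flagged
as disproportionately over-represented — the pattern expected when one
gene's expression dominates many joint-gene signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneCatalog, RegionDefinition
from .exceptions import CatalogError, ParameterError


@dataclass
class MembershipCounts:
    """Per-gene significant-pair membership counts for one trait-region.

    ``table`` columns: gene_id, count, overrepresented, single_significant,
    single_rank (NaN when not significant); genes appear in chromosomal
    order, including zero-count genes.
    """

    region_id: str
    table: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.table["count"].sum())


def count_pair_memberships(
    significant_pairs: Sequence[tuple[str, str]],
    region: RegionDefinition,
    catalog: GeneCatalog,
) -> MembershipCounts:
    """Count, per region gene, membership in deduplicated significant pairs.

    Each unordered pair increments both members by one; region genes with
    no appearances are kept with count 0. A pair naming a gene outside
    the catalog/region raises.
    """
    order = (
        catalog.subset(region.member_gene_ids)
        .genes.sort_values(["chrom", "start"])["gene_id"]
        .tolist()
    )
    known = set(order)
    counts = {g: 0 for g in order}
    seen = set()
    for a, b in significant_pairs:
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        for g in (a, b):
            if g not in known:
                raise CatalogError(g)
            counts[g] += 1
    table = pd.DataFrame(
        {
            "gene_id": order,
            "count": [counts[g] for g in order],
            "overrepresented": False,
            "single_significant": False,
            "single_rank": np.nan,
        }
    )
    return MembershipCounts(region_id=region.region_id, table=table)


def flag_overrepresented(counts: MembershipCounts, k_sd: float = 2.5) -> set[str]:
    """Genes with count strictly above mean + k_sd * sample SD.

    The mean and (n-1) SD are taken over all region genes including
    zero counts. With zero SD no gene can exceed the threshold.
    """
    c = counts.table["count"].to_numpy(dtype=float)
    if c.size < 2:
        raise ParameterError("need at least 2 genes to assess overrepresentation")
    sd = c.std(ddof=1)
    threshold = c.mean() + k_sd * sd
    flagged = set(counts.table.loc[counts.table["count"] > threshold, "gene_id"])
    counts.table["overrepresented"] = counts.table["gene_id"].isin(flagged)
    return flagged


def annotate_single_gene_status(
    counts: MembershipCounts,
    single_gene_pvalues: Mapping[str, float],
    threshold: float,
) -> MembershipCounts:
    """Flag genes significant in the single-gene model and rank them.

    Ranks (1 = smallest p) are assigned by ascending p among the
    significant genes only.
    """
    table = counts.table
    pvals = table["gene_id"].map(lambda g: single_gene_pvalues.get(g, np.nan))
    sig = pvals < threshold
    table["single_significant"] = sig.fillna(False)
    table["single_rank"] = np.nan
    sig_idx = table.index[table["single_significant"]]
    ranked = pvals.loc[sig_idx].rank(method="first")
    table.loc[sig_idx, "single_rank"] = ranked
    return counts
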