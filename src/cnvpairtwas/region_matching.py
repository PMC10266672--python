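"""Matched control gene sets for permutation-based significance testing.

Candidates are contiguous windows of genes (in genomic order, per
chromosome) with exactly the target region's gene count. A window is
accepted when all of the following hold, every bound inclusive:

1. gene count equals the target's (by construction);
2. physical span (first gene start to last gene end) is within 80-120%
   of the target region's length;
3. its coding:noncoding gene ratio is at least 80% of the target's —
   a guard against picking up dense stretches of noncoding genes; when
   the target itself has no noncoding genes the ratio is undefined and
   the criterion degenerates to "the candidate must also have none;"
4. it overlaps neither the target region nor any configured exclusion
   region, nor a previously accepted window (greedy left-to-right scan).

The result is a deterministic function of its inputs — no randomness.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .catalog import GeneCatalog, RegionDefinition
from .exceptions import ParameterError

logger = logging.getLogger(__name__)


def _window_ratio_ok(
    coding: int, noncoding: int, target_coding: int, target_noncoding: int,
    ratio_min_fraction: float,
) -> bool:
    if target_noncoding == 0:
        return noncoding == 0
    if noncoding == 0:
        # candidate ratio is +inf, which exceeds any finite threshold
        return True
    target_ratio = target_coding / target_noncoding
    return coding / noncoding >= ratio_min_fraction * target_ratio


def match_control_regions(
    target: RegionDefinition,
    catalog: GeneCatalog,
    *,
    length_bounds: tuple[float, float] = (0.8, 1.2),
    ratio_min_fraction: float = 0.8,
    exclusions: Sequence[RegionDefinition] = (),
    max_regions: int | None = None,
) -> list[RegionDefinition]:
    """Select control gene windows matched to ``target``.

    Returns accepted windows as :class:`RegionDefinition` objects named
    ``CTRL_<k>`` whose interval is the span from the first member's start
    to the last member's end. An empty result is legal (logged).
    """
    lo_f, hi_f = length_bounds
    if not (0 < lo_f <= hi_f):
        raise ParameterError("length_bounds must be positive and ordered")
    m = len(target.member_gene_ids)
    t_coding, t_noncoding = target.coding_noncoding_counts(catalog)
    t_len = target.length

    accepted: list[RegionDefinition] = []
    for chrom, sub in catalog.genes.groupby("chrom", sort=True):
        sub = sub.sort_values("start").reset_index(drop=True)
        if len(sub) < m:
            continue
        last_accepted_end = None
        for i in range(len(sub) - m + 1):
            window = sub.iloc[i : i + m]
            start = int(window["start"].iloc[0])
            end = int(window["end"].iloc[-1])
            length = end - start
            if not (lo_f * t_len <= length <= hi_f * t_len):
                continue
            coding = int(window["coding"].sum())
            noncoding = m - coding
            if not _window_ratio_ok(
                coding, noncoding, t_coding, t_noncoding, ratio_min_fraction
            ):
                continue
            if target.overlaps(chrom, start, end):
                continue
            if any(ex.overlaps(chrom, start, end) for ex in exclusions):
                continue
            if last_accepted_end is not None and start < last_accepted_end:
                continue  # greedy non-overlap with the previous acceptance
            accepted.append(
                RegionDefinition(
                    region_id=f"CTRL_{len(accepted) + 1:03d}",
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    member_gene_ids=window["gene_id"].tolist(),
                    flank_bp=target.flank_bp,
                )
            )
            last_accepted_end = end
            if max_regions is not None and len(accepted) >= max_regions:
                return accepted
    if not accepted:
        logger.warning(
            "no control windows matched region %s (n=%d, len=%d)",
            target.region_id,
            m,
            t_len,
        )
    return accepted
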