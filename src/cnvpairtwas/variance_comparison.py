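"""Adjusted-R2 comparison of single, pairwise and interaction trait models.

For each tissue-cohort pair three linear designs predict the trait from
imputed expression of a region's units (covariates included in all
three): all single genes; all pairwise joint genes; and the interaction
design (single-gene main effects plus one product term per evaluated
pair). The design with the greatest adjusted R2 wins the tissue-cohort
row; winner proportions in the CNV region versus matched controls are
compared with a Pearson chi-square test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import ols_rss
from .exceptions import ParameterError
from .phenotypes import PhenotypeTable

logger = logging.getLogger(__name__)

WINNERS = ("single", "interaction", "pairwise")
#: tie-break priority, conservative against the pairwise hypothesis
_TIE_ORDER = {"single": 0, "interaction": 1, "pairwise": 2}


def adjusted_r2(y: np.ndarray, x: np.ndarray) -> float:
    """Adjusted R2 of OLS of ``y`` on ``x`` plus an intercept.

    adjusted = 1 - (1 - R2) (n - 1) / (n - k - 1) with k predictors.
    Returns NaN (a not-available marker) when n <= k + 1; callers
    exclude such rows.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    if n != y.size:
        raise ParameterError("y and design have different sample counts")
    if n <= k + 1:
        return float("nan")
    design = np.column_stack([np.ones(n), x])
    rss, _ = ols_rss(y, design)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return float("nan")
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


@dataclass
class TallyRow:
    """Winner record for one tissue-cohort pair at one region."""

    cohort_id: str
    tissue_id: str
    region_id: str
    adj_r2_single: float
    adj_r2_interaction: float
    adj_r2_pairwise: float
    winner: str

    def __post_init__(self) -> None:
        if self.winner not in WINNERS:
            raise ParameterError(f"unknown winner {self.winner!r}")


def _standardize_columns(m: np.ndarray) -> np.ndarray:
    sd = m.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (m - m.mean(axis=0)) / sd


def _winner(values: dict[str, float]) -> str:
    best = max(values.values())
    tied = [k for k, v in values.items() if v == best]
    return min(tied, key=_TIE_ORDER.__getitem__)


def tally_best_models(
    single_predictions: Mapping[tuple[str, str], pd.DataFrame],
    pair_predictions: Mapping[tuple[str, str], pd.DataFrame],
    phenotypes: Mapping[str, PhenotypeTable],
    region_id: str,
    *,
    interaction_main_effects: bool = True,
) -> list[TallyRow]:
    """One winner per tissue-cohort pair.

    ``single_predictions`` / ``pair_predictions`` map (cohort_id,
    tissue_id) to a samples x units prediction DataFrame. The interaction
    design uses products of standardized single predictions for each
    evaluated pair (pair unit ids of the form "A|B" select the columns),
    with main effects included unless ``interaction_main_effects`` is
    False. Tissue-cohort pairs where any design has n <= k + 1 are
    excluded (logged).
    """
    rows: list[TallyRow] = []
    for key in sorted(single_predictions):
        cohort_id, tissue_id = key
        if key not in pair_predictions:
            continue
        singles = single_predictions[key]
        pairs = pair_predictions[key]
        pheno = phenotypes[cohort_id]
        y = pheno.values
        cov = pheno.covariate_matrix()

        s_mat = singles.to_numpy(dtype=float)
        p_mat = pairs.to_numpy(dtype=float)
        s_std = _standardize_columns(s_mat)
        prod_cols = []
        col_of = {g: i for i, g in enumerate(singles.columns)}
        for pid in pairs.columns:
            ga, _, gb = pid.partition("|")
            if ga in col_of and gb in col_of:
                prod_cols.append(s_std[:, col_of[ga]] * s_std[:, col_of[gb]])
        if not prod_cols:
            logger.warning("%s/%s: no interaction terms constructible", cohort_id, tissue_id)
            continue
        inter_parts = [np.column_stack(prod_cols)]
        if interaction_main_effects:
            inter_parts.insert(0, s_mat)
        designs = {
            "single": np.column_stack([s_mat, cov]) if cov.size else s_mat,
            "pairwise": np.column_stack([p_mat, cov]) if cov.size else p_mat,
            "interaction": np.column_stack(inter_parts + ([cov] if cov.size else [])),
        }
        values = {name: adjusted_r2(y, x) for name, x in designs.items()}
        if any(np.isnan(v) for v in values.values()):
            logger.warning("%s/%s: design too large for n, row excluded", cohort_id, tissue_id)
            continue
        rows.append(
            TallyRow(
                cohort_id=cohort_id,
                tissue_id=tissue_id,
                region_id=region_id,
                adj_r2_single=values["single"],
                adj_r2_interaction=values["interaction"],
                adj_r2_pairwise=values["pairwise"],
                winner=_winner(values),
            )
        )
    return rows


def compare_regions(
    cnv_rows: Sequence[TallyRow], control_rows: Sequence[TallyRow]
) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on the 2x2 table
    {CNV, control} x {pairwise-best, not pairwise-best}.

    Raises on a zero margin (the test is undefined there).
    """
    def counts(rows: Sequence[TallyRow]) -> tuple[int, int]:
        pw = sum(1 for r in rows if r.winner == "pairwise")
        return pw, len(rows) - pw

    table = np.array([counts(cnv_rows), counts(control_rows)], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ParameterError("chi-square undefined: a table margin is zero")
    statistic, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(statistic), float(p)


def tally_frame(rows: Sequence[TallyRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.cohort_id,
                r.tissue_id,
                r.region_id,
                r.adj_r2_single,
                r.adj_r2_interaction,
                r.adj_r2_pairwise,
                r.winner,
            )
            for r in rows
        ],
        columns=[
            "cohort",
            "tissue",
            "region",
            "adj_r2_single",
            "adj_r2_interaction",
            "adj_r2_pairwise",
            "winner",
        ],
    )
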