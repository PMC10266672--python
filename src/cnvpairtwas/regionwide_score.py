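"""Region-wide polygenic rank score.

Per gene, an individual's predicted expression is converted to a
normalized rank (rank/(n+1), tie-averaged) within each tissue; the
median across tissues gives the gene-specific ranking. The sum of an
individual's gene-specific rankings is their region-wide score, itself
converted to a normalized (0, 1] rank. Quantitative traits are tested by
Pearson correlation of score with phenotype; binary traits by a
two-sample Kolmogorov-Smirnov test and a Welch t-test of case versus
control scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .phenotypes import PhenotypeTable
from .transforms import normalized_rank

logger = logging.getLogger(__name__)


def per_gene_rank(predictions_by_tissue: Mapping[str, np.ndarray]) -> np.ndarray:
    """Median across tissues of the per-tissue normalized rank.

    With a single tissue this is simply that tissue's rank/(n+1).
    """
    if not predictions_by_tissue:
        raise ParameterError("gene has no retained model in any tissue")
    ranks = np.column_stack(
        [normalized_rank(v) for _, v in sorted(predictions_by_tissue.items())]
    )
    return np.median(ranks, axis=1)


@dataclass
class ScoreTable:
    """Per-individual region-wide scores plus the per-gene ranks."""

    sample_ids: list[str]
    scores: np.ndarray
    gene_ranks: pd.DataFrame  # samples x genes median ranks

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "score": self.scores})


def regionwide_score(
    gene_ranks: Mapping[str, np.ndarray] | pd.DataFrame,
    sample_ids: Sequence[str] | None = None,
) -> ScoreTable:
    """Normalized rank of the per-individual sum of gene-specific ranks."""
    if isinstance(gene_ranks, pd.DataFrame):
        frame = gene_ranks.copy()
    else:
        frame = pd.DataFrame(dict(gene_ranks))
    if frame.shape[1] == 0:
        raise ParameterError("region-wide score needs at least one included gene")
    totals = frame.to_numpy(dtype=float).sum(axis=1)
    scores = normalized_rank(totals)
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in frame.index]
    return ScoreTable(sample_ids=ids, scores=scores, gene_ranks=frame)


def score_trait_association(
    scores: ScoreTable | np.ndarray, phenotype: PhenotypeTable
) -> dict[str, float]:
    """Score-trait tests: Pearson (quantitative) or KS + Welch t (binary)."""
    s = scores.scores if isinstance(scores, ScoreTable) else np.asarray(scores, float)
    y = phenotype.values
    if s.shape != y.shape:
        raise ParameterError("scores and phenotype do not align")
    out: dict[str, float] = {}
    if phenotype.trait_type == "quantitative":
        r, p = stats.pearsonr(s, y)
        out["pearson_r"] = float(r)
        out["pearson_p"] = float(max(p, np.nextafter(0, 1)))
    else:
        cases = s[y == 1]
        controls = s[y == 0]
        if cases.size == 0 or controls.size == 0:
            raise ParameterError("binary phenotype has a single class")
        ks_stat, ks_p = stats.ks_2samp(cases, controls)
        t_stat, t_p = stats.ttest_ind(cases, controls, equal_var=False)
        out.update(
            ks_stat=float(ks_stat),
            ks_p=float(max(ks_p, np.nextafter(0, 1))),
            t_stat=float(t_stat),
            t_p=float(max(t_p, np.nextafter(0, 1))),
        )
    return out


def decile_summary(
    scores: ScoreTable | np.ndarray, phenotype: PhenotypeTable
) -> pd.DataFrame:
    """Mean phenotype (with SE) within score deciles.

    Individuals are sorted by score and cut into 10 near-equal bins; when
    n is not divisible by 10 the remainder is spread over the lowest
    bins, so bin sizes differ by at most one and sum to n.
    """
    s = scores.scores if isinstance(scores, ScoreTable) else np.asarray(scores, float)
    y = phenotype.values
    n = s.size
    if n < 10:
        raise ParameterError("decile summary needs at least 10 individuals")
    order = np.argsort(s, kind="stable")
    base, rem = divmod(n, 10)
    sizes = [base + (1 if i < rem else 0) for i in range(10)]
    rows = []
    pos = 0
    for d, size in enumerate(sizes, start=1):
        idx = order[pos : pos + size]
        pos += size
        vals = y[idx]
        se = float(vals.std(ddof=1) / np.sqrt(size)) if size > 1 else float("nan")
        rows.append((d, size, float(vals.mean()), se))
    return pd.DataFrame(rows, columns=["decile", "n", "mean", "se"])
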