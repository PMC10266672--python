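"""Elastic-net SNP-weight models for single genes and pairwise joint genes.

A "joint gene" is a synthetic expression unit defined as the rank-based
inverse normal transform of the sum of two genes' expression in the same
tissue; it is trained exactly like a single gene. Weights are fitted on
within-panel standardized dosages (mixing parameter fixed, penalty chosen
by seeded k-fold cross-validation minimising mean CV error) and stored on
the standardized scale together with the training-panel mean/SD of each
SNP so that predictions are reproducible in any cohort.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold, cross_val_predict

from .catalog import GeneCatalog, RegionDefinition
from .exceptions import DegenerateInputError, ParameterError
from .genotypes import GenotypePanel
from .transforms import inverse_normal_transform

logger = logging.getLogger(__name__)

WEIGHT_COLUMNS = ["variant_id", "effect_allele", "ref_allele", "weight", "train_mean", "train_sd"]

#: default cis window around a gene for candidate SNPs, in bases
DEFAULT_CIS_WINDOW_BP = 100_000


@dataclass
class WeightModel:
    """Sparse SNP-weight model for one (unit, tissue).

    ``unit_id`` is a gene id or ``"geneA|geneB"`` with the two genes in
    genomic order. ``weights`` holds only nonzero-weight variants.
    """

    unit_id: str
    tissue_id: str
    weights: pd.DataFrame
    cv_performance_r2: float
    cv_p: float

    def __post_init__(self) -> None:
        if len(self.weights) == 0:
            self.weights = pd.DataFrame(columns=WEIGHT_COLUMNS)
        missing = [c for c in WEIGHT_COLUMNS if c not in self.weights.columns]
        if missing:
            raise ParameterError(f"weight table missing columns: {missing}")
        self.weights = self.weights[WEIGHT_COLUMNS].reset_index(drop=True)
        if (self.weights["weight"].to_numpy() == 0).any():
            raise ParameterError("stored weights must all be nonzero")
        if not 0.0 < self.cv_p <= 1.0:
            raise ParameterError("cv_p must lie in (0, 1]")

    @property
    def n_snps_in_model(self) -> int:
        return len(self.weights)

    def weight_arrays(self) -> tuple[np.ndarray, ...]:
        """Cached numpy views (variant_id, effect, ref, weight, mean, sd)."""
        arrs = getattr(self, "_arrays", None)
        if arrs is None:
            w = self.weights
            arrs = (
                w["variant_id"].to_numpy(),
                w["effect_allele"].to_numpy(),
                w["ref_allele"].to_numpy(),
                w["weight"].to_numpy(dtype=float),
                w["train_mean"].to_numpy(dtype=float),
                w["train_sd"].to_numpy(dtype=float),
            )
            object.__setattr__(self, "_arrays", arrs)
        return arrs

    @property
    def is_empty(self) -> bool:
        return len(self.weights) == 0

    @property
    def is_pair(self) -> bool:
        return "|" in self.unit_id


def pair_unit_id(gene_a: str, gene_b: str, catalog: GeneCatalog) -> str:
    """Canonical pair id with members ordered by genomic position."""
    if gene_a == gene_b:
        raise ParameterError("a pair must consist of two distinct genes")
    ga, gb = catalog.gene(gene_a), catalog.gene(gene_b)
    first, second = sorted(
        [(ga["chrom"], ga["start"], gene_a), (gb["chrom"], gb["start"], gene_b)]
    )
    return f"{first[2]}|{second[2]}"


def enumerate_pairs(
    region: RegionDefinition, catalog: GeneCatalog
) -> list[tuple[str, str]]:
    """All unordered gene pairs of a region, in genomic order."""
    sub = catalog.subset(region.member_gene_ids).genes
    ids = sub.sort_values(["chrom", "start"])["gene_id"].tolist()
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


def make_pair_target(expr_a: np.ndarray, expr_b: np.ndarray) -> np.ndarray:
    """Joint-gene target: INT of the sum of two expression vectors."""
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("pair expression vectors must share the sample set")
    total = a + b
    if np.ptp(total) == 0:
        raise DegenerateInputError("pair expression sum is constant")
    return inverse_normal_transform(total)


def train_weight_model(
    dosages: pd.DataFrame,
    target_expr: np.ndarray,
    variant_info: pd.DataFrame,
    *,
    unit_id: str,
    tissue_id: str,
    snp_allowlist: Sequence[str] | None = None,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 25,
) -> WeightModel:
    """Fit an elastic-net SNP model for one expression unit.

    Parameters
    ----------
    dosages
        Samples x candidate-variants dosage DataFrame (columns are
        variant ids, already restricted to the unit's cis window).
    target_expr
        Expression vector over the same samples.
    variant_info
        Indexed by variant_id with effect_allele / ref_allele columns.
    snp_allowlist
        If given, candidates are intersected with this list (per-dataset
        SNP restriction).
    alpha
        Elastic-net mixing parameter (lasso fraction); the penalty
        strength is chosen by ``n_folds``-fold CV minimising mean CV
        error, with the fold assignment seeded for determinism.

    ``cv_performance_r2`` is the squared Pearson correlation between the
    out-of-fold predictions at the chosen penalty and the target; ``cv_p``
    its correlation-test p-value. An empty candidate set, or a fit that
    selects no SNPs, yields an empty (flagged) model rather than an error.
    """
    y = np.asarray(target_expr, dtype=float)
    if snp_allowlist is not None:
        keep = [c for c in dosages.columns if c in set(snp_allowlist)]
        dosages = dosages[keep]
    n, k = dosages.shape
    if n != y.size:
        raise ParameterError("dosage rows and target length differ")
    if k == 0:
        logger.warning("unit %s/%s: no candidate SNPs; empty model", unit_id, tissue_id)
        return WeightModel(unit_id, tissue_id, pd.DataFrame(), 0.0, 1.0)
    if n < n_folds:
        raise ParameterError(f"need at least n_folds={n_folds} samples, got {n}")

    x = dosages.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    informative = sd > 0
    x_std = np.zeros_like(x)
    x_std[:, informative] = (x[:, informative] - mean[informative]) / sd[informative]

    # nested CV: the penalty is re-selected inside every training fold,
    # so the out-of-fold performance estimate never sees data that
    # influenced the penalty choice (a shared split makes null targets
    # look predictive); the stored weights come from a full-data fit
    folds_inner = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds_eval = KFold(n_splits=n_folds, shuffle=True, random_state=seed + 1)
    final = ElasticNetCV(
        l1_ratio=alpha,
        alphas=n_alphas,  # length of the automatic penalty path
        cv=folds_inner,
        max_iter=5000,
        random_state=seed,
    )
    with np.errstate(all="ignore"):
        oof = cross_val_predict(clone(final), x_std, y, cv=folds_eval)
        final.fit(x_std, y)

    # demean within evaluation folds: the per-fold intercept of an OOF
    # prediction is the complement folds' mean, which is systematically
    # anti-correlated with the held-out target and would make null
    # models look predictive
    oof_c = oof.astype(float).copy()
    y_c = y.astype(float).copy()
    for _, test_idx in folds_eval.split(x_std):
        oof_c[test_idx] -= oof_c[test_idx].mean()
        y_c[test_idx] -= y_c[test_idx].mean()
    if np.ptp(oof_c) == 0:
        cv_r2, cv_p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(oof_c, y_c)
        cv_r2 = float(r * r)
        cv_p = float(np.clip(p, np.nextafter(0, 1), 1.0))

    nz = np.flatnonzero(final.coef_)
    cols = list(dosages.columns)
    info = variant_info.set_index("variant_id") if "variant_id" in variant_info.columns else variant_info
    rows = []
    for j in nz:
        vid = cols[j]
        rows.append(
            (
                vid,
                info.loc[vid, "effect_allele"],
                info.loc[vid, "ref_allele"],
                float(final.coef_[j]),
                float(mean[j]),
                float(sd[j]),
            )
        )
    weights = pd.DataFrame(rows, columns=WEIGHT_COLUMNS)
    if len(weights) == 0:
        logger.info("unit %s/%s: elastic net selected no SNPs", unit_id, tissue_id)
    return WeightModel(unit_id, tissue_id, weights, cv_r2, cv_p)


def filter_models(
    models: Iterable[WeightModel], r2_min: float = 0.01, p_max: float = 0.05
) -> list[WeightModel]:
    """Keep exactly the models with cv R2 > ``r2_min`` and cv p < ``p_max``."""
    return [m for m in models if m.cv_performance_r2 > r2_min and m.cv_p < p_max]


def _unit_seed(base_seed: int, unit_id: str, tissue_id: str) -> int:
    return (base_seed ^ zlib.crc32(f"{unit_id}|{tissue_id}".encode())) % (2**31)


def train_region_models(
    panel: GenotypePanel,
    expression: "ExpressionPanelLike",
    catalog: GeneCatalog,
    region: RegionDefinition,
    *,
    include_singles: bool = True,
    include_pairs: bool = True,
    snp_allowlist: Sequence[str] | None = None,
    cis_window_bp: int = DEFAULT_CIS_WINDOW_BP,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 25,
) -> list[WeightModel]:
    """Train single-gene and joint-gene models for every unit of a region.

    Pair candidate SNPs are the union of the two members' cis windows.
    Degenerate pairs (constant expression sum) are skipped with a log
    message rather than failing the whole region.
    """
    models: list[WeightModel] = []
    sub = catalog.subset(region.member_gene_ids).genes

    def cis_frame(gene_rows) -> pd.DataFrame:
        vids: list[str] = []
        for g in gene_rows.itertuples(index=False):
            vids.extend(panel.cis_variant_ids(g.chrom, g.start, g.end, cis_window_bp))
        vids = list(dict.fromkeys(vids))
        return panel.dosage_frame(vids)

    if include_singles:
        for g in sub.itertuples(index=False):
            for t in expression.tissues_for(g.gene_id):
                target = expression.expression[(t, g.gene_id)]
                models.append(
                    train_weight_model(
                        cis_frame(sub[sub["gene_id"] == g.gene_id]),
                        target,
                        panel.variants,
                        unit_id=g.gene_id,
                        tissue_id=t,
                        snp_allowlist=snp_allowlist,
                        alpha=alpha,
                        n_folds=n_folds,
                        seed=_unit_seed(seed, g.gene_id, t),
                        n_alphas=n_alphas,
                    )
                )
    if include_pairs:
        for ga, gb in enumerate_pairs(region, catalog):
            uid = pair_unit_id(ga, gb, catalog)
            shared_tissues = sorted(
                set(expression.tissues_for(ga)) & set(expression.tissues_for(gb))
            )
            for t in shared_tissues:
                try:
                    target = make_pair_target(
                        expression.expression[(t, ga)], expression.expression[(t, gb)]
                    )
                except DegenerateInputError:
                    logger.warning("skipping degenerate pair %s in %s", uid, t)
                    continue
                models.append(
                    train_weight_model(
                        cis_frame(sub[sub["gene_id"].isin([ga, gb])]),
                        target,
                        panel.variants,
                        unit_id=uid,
                        tissue_id=t,
                        snp_allowlist=snp_allowlist,
                        alpha=alpha,
                        n_folds=n_folds,
                        seed=_unit_seed(seed, uid, t),
                        n_alphas=n_alphas,
                    )
                )
    return models


# --------------------------------------------------------------------------
# weight store (PredictDB-like two-table TSV layout)
# --------------------------------------------------------------------------
def write_weight_models(
    models: Sequence[WeightModel],
    weights_path: str | Path,
    extra_path: str | Path,
) -> None:
    """Serialize models as a weights table and an 'extra' summary table."""
    wrows = []
    erows = []
    for m in models:
        for r in m.weights.itertuples(index=False):
            wrows.append(
                (
                    m.unit_id,
                    m.tissue_id,
                    r.variant_id,
                    r.effect_allele,
                    r.ref_allele,
                    r.weight,
                    r.train_mean,
                    r.train_sd,
                )
            )
        erows.append(
            (m.unit_id, m.tissue_id, m.cv_performance_r2, m.cv_p, m.n_snps_in_model)
        )
    pd.DataFrame(
        wrows,
        columns=[
            "unit_id",
            "tissue_id",
            "variant_id",
            "effect_allele",
            "ref_allele",
            "weight",
            "train_mean",
            "train_sd",
        ],
    ).to_csv(weights_path, sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(
        erows,
        columns=["unit_id", "tissue_id", "pred_perf_R2", "pred_perf_pval", "n_snps_in_model"],
    ).to_csv(extra_path, sep="\t", index=False, float_format="%.17g")


def read_weight_models(
    weights_path: str | Path, extra_path: str | Path
) -> list[WeightModel]:
    wdf = pd.read_csv(weights_path, sep="\t", float_precision="round_trip")
    edf = pd.read_csv(extra_path, sep="\t", float_precision="round_trip")
    grouped: dict[tuple[str, str], pd.DataFrame] = {
        key: sub for key, sub in wdf.groupby(["unit_id", "tissue_id"], sort=False)
    }
    models = []
    for row in edf.itertuples(index=False):
        key = (row.unit_id, row.tissue_id)
        sub = grouped.get(key)
        weights = (
            sub[WEIGHT_COLUMNS].copy() if sub is not None else pd.DataFrame(columns=WEIGHT_COLUMNS)
        )
        models.append(
            WeightModel(
                unit_id=row.unit_id,
                tissue_id=row.tissue_id,
                weights=weights,
                cv_performance_r2=float(row.pred_perf_R2),
                cv_p=float(row.pred_perf_pval),
            )
        )
    return models


class ExpressionPanelLike:
    """Protocol-ish duck type: needs .expression dict and .tissues_for()."""
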