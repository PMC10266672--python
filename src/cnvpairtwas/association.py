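"""Association of predicted expression units with traits.

The stages mirror the standard individual-level and summary-level TWAS
tool chain:

* ``predict_expression`` — apply a SNP-weight model to a dosage panel with
  allele harmonization (the individual-level predictor);
* ``associate_tissue`` — linear association of a trait with one tissue's
  prediction, adjusting for covariates;
* ``spredixcan_z`` — the summary-statistics equivalent, combining
  per-variant GWAS z-scores through the model weights with an LD
  reference panel;
* ``combine_tissues_individual`` / ``combine_tissues_summary`` — the
  cross-tissue combination (principal components of the per-tissue
  predictions, F-test; or the eigen-projected chi-square on per-tissue
  z-scores);
* ``meta_analyze`` — sample-size-weighted z-score meta-analysis across
  cohorts (p-value + direction + N scheme);
* ``permutation_threshold`` — the empirical significance threshold: the
  median across matched control regions of each region's 5th-percentile
  association p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from ._stats import linear_association, nested_f_test
from .exceptions import (
    DegenerateInputError,
    NumericalInputError,
    ParameterError,
)
from .expression_models import WeightModel
from .genotypes import GenotypePanel
from .phenotypes import PhenotypeTable, SummaryStats

logger = logging.getLogger(__name__)

_TINY_P = 1e-300
LOW_COVERAGE = 0.5


@dataclass
class AssociationRecord:
    """One unit-trait association at tissue, cross-tissue or meta level."""

    unit_id: str
    trait: str
    level: str  # "tissue" | "cross_tissue" | "meta"
    effect: float
    p: float
    direction: int
    se: float | None = None
    tissue_id: str | None = None
    cohort_id: str | None = None
    n_effective: float | None = None
    coverage: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ParameterError(f"p must lie in (0, 1], got {self.p}")
        if self.direction not in (-1, 0, 1):
            raise ParameterError("direction must be -1, 0 or +1")

    @property
    def low_coverage(self) -> bool:
        return self.coverage is not None and self.coverage < LOW_COVERAGE


@dataclass
class PredictionResult:
    """Predicted expression for one unit in one cohort."""

    unit_id: str
    tissue_id: str
    values: np.ndarray | None
    coverage: float

    @property
    def missing(self) -> bool:
        return self.values is None


def _harmonized_standardized_dosages(
    model: WeightModel, panel: GenotypePanel
) -> tuple[np.ndarray, np.ndarray, int]:
    """Standardized (training-scale) dosages for the model SNPs present.

    Returns (matrix n x k_used, weights k_used, n_model_snps). Variants
    absent from the panel, with irreconcilable alleles, or with zero
    training SD are skipped — never imputed.
    """
    vids, m_eff, m_ref, m_w, m_mean, m_sd = model.weight_arrays()
    pos = panel.variant_positions(vids)
    found = pos >= 0
    if not found.any():
        return np.zeros((panel.n_samples, 0)), np.zeros(0), model.n_snps_in_model
    p_eff_all, p_ref_all = panel.allele_arrays()
    p_eff = p_eff_all[pos[found]]
    p_ref = p_ref_all[pos[found]]
    same = (m_eff[found] == p_eff) & (m_ref[found] == p_ref)
    swapped = (m_eff[found] == p_ref) & (m_ref[found] == p_eff)
    usable = (same | swapped) & (m_sd[found] > 0)
    if not usable.any():
        return np.zeros((panel.n_samples, 0)), np.zeros(0), model.n_snps_in_model
    d = panel.dosages[:, pos[found][usable]].astype(float)
    flip = swapped[usable]
    d[:, flip] = 2.0 - d[:, flip]
    x = (d - m_mean[found][usable]) / m_sd[found][usable]
    return x, m_w[found][usable], model.n_snps_in_model


def predict_expression(model: WeightModel, panel: GenotypePanel) -> PredictionResult:
    """Predict a unit's expression in a cohort: sum of weight x dosage.

    Dosages are harmonized to the model's effect alleles (flipped 2 - d
    on an allele swap) and standardized with the training-panel mean/SD.
    ``coverage`` is the fraction of model SNPs found; a unit with no
    usable SNPs yields a missing prediction (skipped downstream, logged).
    """
    x, w, n_total = _harmonized_standardized_dosages(model, panel)
    if n_total == 0 or x.shape[1] == 0:
        logger.info(
            "unit %s/%s: no model SNPs present in cohort", model.unit_id, model.tissue_id
        )
        return PredictionResult(model.unit_id, model.tissue_id, None, 0.0)
    coverage = x.shape[1] / n_total
    return PredictionResult(model.unit_id, model.tissue_id, x @ w, coverage)


def associate_tissue(
    prediction: PredictionResult | np.ndarray,
    phenotype: PhenotypeTable,
    *,
    unit_id: str = "",
    tissue_id: str | None = None,
    cohort_id: str | None = None,
) -> AssociationRecord | None:
    """Linear association of a trait with one tissue's prediction.

    Binary traits are regressed on 0/1. Returns None (with a warning)
    when the prediction is missing or constant.
    """
    coverage = None
    if isinstance(prediction, PredictionResult):
        unit_id = unit_id or prediction.unit_id
        tissue_id = tissue_id or prediction.tissue_id
        coverage = prediction.coverage
        if prediction.missing:
            return None
        x = prediction.values
    else:
        x = np.asarray(prediction, dtype=float)
    try:
        res = linear_association(
            phenotype.values, x, phenotype.covariate_matrix()
        )
    except DegenerateInputError:
        logger.warning("unit %s/%s: constant prediction, skipped", unit_id, tissue_id)
        return None
    return AssociationRecord(
        unit_id=unit_id,
        trait=phenotype.trait_name,
        level="tissue",
        effect=res.beta,
        se=res.se,
        p=res.p,
        direction=int(np.sign(res.beta)),
        tissue_id=tissue_id,
        cohort_id=cohort_id,
        n_effective=phenotype.n,
        coverage=coverage,
    )


def spredixcan_z(
    model: WeightModel,
    sumstats: SummaryStats,
    reference: GenotypePanel,
    *,
    trait: str = "trait",
    cohort_id: str | None = None,
) -> AssociationRecord | None:
    """Summary-statistics association of one unit.

    z_unit = sum_l w_l sigma_l z_l / sigma_unit with sigma_unit^2 =
    w' Gamma w, where Gamma is the covariance of the model SNPs'
    standardized dosages in the reference panel (so sigma_l = 1 on the
    standardized scale) and z_l = beta_l / se_l after harmonizing the
    summary statistics to the model's effect alleles.
    """
    ss = sumstats.indexed()
    x_cols = []
    w_used = []
    z_used = []
    n_vals = []
    ref_v = reference.variants.set_index("variant_id")
    for r in model.weights.itertuples(index=False):
        if r.variant_id not in ss.index or r.variant_id not in ref_v.index:
            continue
        srow = ss.loc[r.variant_id]
        z = float(srow["beta"]) / float(srow["se"])
        if srow["effect_allele"] == r.effect_allele and srow["other_allele"] == r.ref_allele:
            pass
        elif srow["effect_allele"] == r.ref_allele and srow["other_allele"] == r.effect_allele:
            z = -z
        else:
            continue
        j = ref_v.index.get_loc(r.variant_id)
        d = reference.dosages[:, j].astype(float)
        rrow = ref_v.iloc[j]
        if r.effect_allele == rrow["effect_allele"]:
            pass
        elif r.effect_allele == rrow["ref_allele"]:
            d = 2.0 - d
        else:
            continue
        sd = d.std()
        if sd == 0:
            continue
        x_cols.append((d - d.mean()) / sd)
        w_used.append(r.weight)
        z_used.append(z)
        n_vals.append(float(srow["n"]))
    if not x_cols:
        logger.info("unit %s/%s: no usable SNPs for summary association", model.unit_id, model.tissue_id)
        return None
    x = np.column_stack(x_cols)
    w = np.asarray(w_used)
    zv = np.asarray(z_used)
    gamma = (x.T @ x) / x.shape[0]
    sigma_unit2 = float(w @ gamma @ w)
    if sigma_unit2 <= 0:
        logger.warning("unit %s/%s: degenerate predictor variance", model.unit_id, model.tissue_id)
        return None
    z_unit = float(w @ zv) / np.sqrt(sigma_unit2)
    p = float(np.clip(2.0 * ndtr(-abs(z_unit)), _TINY_P, 1.0))
    return AssociationRecord(
        unit_id=model.unit_id,
        trait=trait,
        level="tissue",
        effect=z_unit,
        p=p,
        direction=int(np.sign(z_unit)),
        tissue_id=model.tissue_id,
        cohort_id=cohort_id,
        n_effective=float(np.mean(n_vals)),
        coverage=len(w_used) / model.n_snps_in_model,
    )


def _retained_components(eigvals: np.ndarray, condition_limit: float) -> np.ndarray:
    lam_max = eigvals.max()
    if lam_max <= 0:
        raise DegenerateInputError("no variance in the prediction matrix")
    with np.errstate(divide="ignore"):
        cond = np.where(eigvals > 0, lam_max / eigvals, np.inf)
    return np.flatnonzero(cond <= condition_limit)


def combine_tissues_individual(
    predictions: Mapping[str, np.ndarray],
    phenotype: PhenotypeTable,
    *,
    unit_id: str = "",
    cohort_id: str | None = None,
    condition_limit: float = 30.0,
) -> AssociationRecord | None:
    """Cross-tissue association from individual-level predictions.

    Principal components of the samples x tissues prediction matrix are
    retained while lambda_max / lambda_i <= ``condition_limit``; the
    trait is regressed on the retained components plus covariates and
    compared with the covariate-only model by an F-test. Direction is
    the sign of the mean per-tissue univariate beta (the quantity fed to
    the downstream meta-analysis).
    """
    tissues = sorted(predictions)
    cols = []
    betas = []
    for t in tissues:
        v = np.asarray(predictions[t], dtype=float)
        if v.std() == 0:
            continue
        cols.append((v - v.mean()) / v.std())
        rec = associate_tissue(v, phenotype, unit_id=unit_id, tissue_id=t)
        if rec is not None:
            betas.append(rec.effect)
    if not cols:
        logger.warning("unit %s: all-tissue predictions degenerate", unit_id)
        return None
    m = np.column_stack(cols)
    n = m.shape[0]
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    eigvals = s**2 / n
    keep = _retained_components(eigvals, condition_limit)
    comps = u[:, keep] * s[keep]
    f, p, df_num, df_den = nested_f_test(
        phenotype.values, comps, phenotype.covariate_matrix()
    )
    mean_beta = float(np.mean(betas)) if betas else 0.0
    return AssociationRecord(
        unit_id=unit_id,
        trait=phenotype.trait_name,
        level="cross_tissue",
        effect=f,
        p=p,
        direction=int(np.sign(mean_beta)),
        cohort_id=cohort_id,
        n_effective=phenotype.n,
    )


def tissue_correlation(predictions: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Correlation of a unit's predicted expression across tissues,
    computed on a reference panel's predictions."""
    tissues = sorted(predictions)
    m = np.column_stack([np.asarray(predictions[t], float) for t in tissues])
    sd = m.std(axis=0)
    if (sd == 0).any():
        bad = [t for t, s in zip(tissues, sd) if s == 0]
        raise DegenerateInputError(f"constant reference prediction in {bad}")
    corr = np.corrcoef(m, rowvar=False)
    return pd.DataFrame(np.atleast_2d(corr), index=tissues, columns=tissues)


def combine_tissues_summary(
    z_by_tissue: Mapping[str, float],
    tissue_corr: pd.DataFrame,
    *,
    unit_id: str = "",
    trait: str = "trait",
    cohort_id: str | None = None,
    condition_limit: float = 30.0,
) -> AssociationRecord:
    """Cross-tissue association from per-tissue summary z-scores.

    The tissue correlation of predicted expression (from a reference
    panel) is eigendecomposed; z is projected on the components with
    lambda_max / lambda_i <= ``condition_limit`` and the squared
    projections, scaled by 1/lambda_i, sum to a chi-square statistic
    with one degree of freedom per retained component.
    """
    tissues = sorted(z_by_tissue)
    corr = tissue_corr.loc[tissues, tissues].to_numpy(dtype=float)
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise NumericalInputError("tissue correlation matrix is not symmetric")
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() < -1e-8:
        raise NumericalInputError("tissue correlation matrix is not PSD")
    eigvals = np.clip(eigvals, 0.0, None)
    keep = _retained_components(eigvals, condition_limit)
    z = np.array([z_by_tissue[t] for t in tissues], dtype=float)
    proj = eigvecs[:, keep].T @ z
    statistic = float(np.sum(proj**2 / eigvals[keep]))
    df = len(keep)
    p = float(np.clip(stats.chi2.sf(statistic, df), _TINY_P, 1.0))
    return AssociationRecord(
        unit_id=unit_id,
        trait=trait,
        level="cross_tissue",
        effect=statistic,
        p=p,
        direction=int(np.sign(z.mean())),
        cohort_id=cohort_id,
        n_effective=float(df),
    )


def meta_analyze(
    records: Sequence[AssociationRecord], n_per_cohort: Sequence[float]
) -> AssociationRecord:
    """Sample-size-weighted z-score meta-analysis across cohorts.

    z_i = Phi^{-1}(1 - p_i / 2) * direction_i, weighted by sqrt(n_i):
    z_meta = sum w_i z_i / sqrt(sum w_i^2). Input p-values of exactly 0
    are clamped to the smallest usable positive value with a warning.
    """
    if len(records) == 0 or len(records) != len(n_per_cohort):
        raise ParameterError("records and per-cohort sample sizes must align")
    zs = []
    for rec in records:
        p = rec.p
        if p < _TINY_P:
            logger.warning("meta input p underflow for %s; clamped", rec.unit_id)
            p = _TINY_P
        # Phi^-1(1 - p/2) computed as -Phi^-1(p/2) to stay finite for
        # p far below machine epsilon
        zs.append(-ndtri(p / 2.0) * rec.direction)
    z = np.asarray(zs)
    w = np.sqrt(np.asarray(n_per_cohort, dtype=float))
    z_meta = float((w * z).sum() / np.sqrt((w**2).sum()))
    p_meta = float(np.clip(2.0 * ndtr(-abs(z_meta)), _TINY_P, 1.0))
    return AssociationRecord(
        unit_id=records[0].unit_id,
        trait=records[0].trait,
        level="meta",
        effect=z_meta,
        p=p_meta,
        direction=int(np.sign(z_meta)),
        n_effective=float(np.sum(n_per_cohort)),
    )


def permutation_threshold(
    control_pvalues: Sequence[Sequence[float]], percentile: float = 5.0
) -> float:
    """Median across control regions of each region's p-value percentile.

    Each element of ``control_pvalues`` is the list of unit p-values from
    one matched control region; the per-region percentile uses linear
    interpolation and the across-region median averages the two middle
    values for an even region count.
    """
    if len(control_pvalues) == 0:
        raise ParameterError("no control regions available for the null")
    per_region = []
    for i, pvals in enumerate(control_pvalues):
        arr = np.asarray(list(pvals), dtype=float)
        if arr.size == 0:
            raise ParameterError(f"control region {i} has no p-values")
        per_region.append(np.percentile(arr, percentile))
    thr = float(np.median(per_region))
    return float(np.clip(thr, np.nextafter(0, 1), np.nextafter(1, 0)))


def prediction_frame(
    models: Sequence[WeightModel],
    panel: GenotypePanel,
    *,
    tissue_id: str,
    pairs: bool | None = None,
) -> pd.DataFrame:
    """Samples x units prediction matrix for one tissue.

    ``pairs`` selects pair units (True), single units (False) or both
    (None). Units with missing predictions are dropped.
    """
    cols = {}
    for m in models:
        if m.tissue_id != tissue_id:
            continue
        if pairs is not None and m.is_pair != pairs:
            continue
        pred = predict_expression(m, panel)
        if pred.missing:
            continue
        cols[m.unit_id] = pred.values
    return pd.DataFrame(cols, index=panel.sample_ids)


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Flatten association records to the output TSV layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "unit_id": r.unit_id,
                "unit_class": "pair" if "|" in r.unit_id else "single",
                "trait": r.trait,
                "level": r.level,
                "cohort": r.cohort_id,
                "tissue": r.tissue_id,
                "effect": r.effect,
                "se": r.se,
                "p": r.p,
                "direction": r.direction,
                "n_effective": r.n_effective,
                "coverage": r.coverage,
            }
        )
    return pd.DataFrame(rows)
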