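"""Simulation studies validating the pipeline end to end.

Each function here runs a self-contained synthetic experiment — null
calibration of the permutation threshold, generative-architecture
recovery for the pairwise and region-wide models, hub-gene
over-representation, elastic-net oracle checks, and summary-versus-
individual internal consistency — and returns the measured rates. They
are consumed both by the test suite and by ``scripts/acceptance.py``.

Problem sizes follow the package's standard study conditions (cohorts of
2000-5000, training panels of ~300, 3 tissues, 8-15 gene regions);
where a stage's model fitting is not itself under study the experiments
use oracle weight models derived from the generative eQTL truth (or
random-weight units for pure null calibration) so that the stage under
study is isolated; elastic-net behaviour is validated separately in
:func:`elasticnet_oracle`.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import (
    CnvSpec,
    EffectSpec,
    EqtlSpec,
    GenotypePanel,
    PhenotypeTable,
    associate_tissue,
    combine_tissues_individual,
    combine_tissues_summary,
    compute_gwas_summary,
    count_pair_memberships,
    filter_models,
    flag_overrepresented,
    generate_gene_catalog,
    match_control_regions,
    permutation_threshold,
    predict_expression,
    simulate_expression_panel,
    simulate_genotype_panel,
    simulate_trait,
    spredixcan_z,
    tissue_correlation,
)
from ._stats import bulk_linear_association, standardize
from .association import prediction_frame
from .catalog import GeneCatalog, RegionDefinition
from .exceptions import ParameterError
from .expression_models import (
    WEIGHT_COLUMNS,
    WeightModel,
    enumerate_pairs,
    pair_unit_id,
    train_region_models,
)
from .regionwide_score import per_gene_rank, regionwide_score, score_trait_association
from .synthetic import EqtlTruth
from .transforms import inverse_normal_transform
from .variance_comparison import compare_regions, tally_best_models

logger = logging.getLogger(__name__)

#: training hyper-parameters used inside the larger simulation studies
#: (fewer folds / shorter penalty path than the library defaults, chosen
#: for experiment turnaround at hundreds of models per run)
_FAST_TRAIN = dict(n_folds=5, n_alphas=15)


def _seed_seq(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _model_from_weights(
    unit_id: str,
    tissue_id: str,
    variant_ids: Sequence[str],
    weights: np.ndarray,
    panel: GenotypePanel,
) -> WeightModel:
    """Build a WeightModel with train stats taken from ``panel``."""
    pos = panel.variant_positions(variant_ids)
    pv = panel.variants.iloc[pos]
    d = panel.dosages[:, pos].astype(float)
    means = d.mean(axis=0)
    sds = d.std(axis=0)
    rows = []
    for j, vid in enumerate(variant_ids):
        if weights[j] == 0:
            continue
        rows.append(
            (
                vid,
                pv["effect_allele"].iloc[j],
                pv["ref_allele"].iloc[j],
                float(weights[j]),
                float(means[j]),
                float(sds[j]) or 1.0,
            )
        )
    return WeightModel(
        unit_id, tissue_id, pd.DataFrame(rows, columns=WEIGHT_COLUMNS), 1.0, float(np.nextafter(0, 1))
    )


def oracle_weight_models(
    truth: EqtlTruth,
    panel: GenotypePanel,
    gene_ids: Sequence[str],
    tissue_ids: Sequence[str],
    *,
    catalog: GeneCatalog | None = None,
    include_pairs: bool = False,
) -> list[WeightModel]:
    """Weight models taken directly from the generative eQTL truth.

    Pair-unit models, when requested, concatenate the two members' truth
    weights so the pair prediction is the sum of the members' genetic
    values — the noise-free analogue of a trained joint-gene model.
    """
    models = []
    for t in tissue_ids:
        for g in gene_ids:
            vids, w = truth.weights[(t, g)]
            models.append(_model_from_weights(g, t, vids, w.copy(), panel))
        if include_pairs:
            if catalog is None:
                raise ParameterError("pair oracle models need the catalog")
            for i in range(len(gene_ids)):
                for j in range(i + 1, len(gene_ids)):
                    ga, gb = gene_ids[i], gene_ids[j]
                    va, wa = truth.weights[(t, ga)]
                    vb, wb = truth.weights[(t, gb)]
                    vids = list(va) + [v for v in vb if v not in set(va)]
                    w = np.zeros(len(vids))
                    pos = {v: k for k, v in enumerate(vids)}
                    for v, x in zip(va, wa):
                        w[pos[v]] += x
                    for v, x in zip(vb, wb):
                        w[pos[v]] += x
                    models.append(
                        _model_from_weights(
                            pair_unit_id(ga, gb, catalog), t, vids, w, panel
                        )
                    )
    return models


def random_weight_models(
    panel: GenotypePanel,
    region: RegionDefinition,
    n_units: int,
    rng: np.random.Generator,
    *,
    tissue_id: str = "T1",
    n_snps: int = 4,
    cis_window_bp: int = 100_000,
    prefix: str = "U",
) -> list[WeightModel]:
    """Arbitrary sparse expression units on a region's cis variants.

    Used for null calibration, where any linear genotype combination is
    a legitimate "unit" and the association p-values are the object
    under study.
    """
    cis = panel.cis_variant_ids(region.chrom, region.start, region.end, cis_window_bp)
    if len(cis) < n_snps:
        raise ParameterError("region has too few cis variants")
    models = []
    for u in range(n_units):
        idx = rng.choice(len(cis), size=n_snps, replace=False)
        w = rng.standard_normal(n_snps)
        w[w == 0] = 1.0
        models.append(
            _model_from_weights(
                f"{region.region_id}_{prefix}{u + 1:03d}",
                tissue_id,
                [cis[i] for i in idx],
                w,
                panel,
            )
        )
    return models


# --------------------------------------------------------------------------
# 1. permutation-threshold calibration under the null
# --------------------------------------------------------------------------
def threshold_calibration(
    seed: int,
    *,
    n_replicates: int = 20,
    n_samples: int = 2000,
    n_control_regions: int = 20,
    n_units: int = 100,
    percentile: float = 5.0,
) -> dict:
    """Fraction of CNV units passing the permutation threshold for a
    null trait; calibrated when the mean fraction is near 5%."""
    seeds = _seed_seq(seed, 2 * n_replicates + 2)
    catalog, region = generate_gene_catalog(500, CnvSpec(), seed=seed)
    controls = match_control_regions(region, catalog, max_regions=n_control_regions)
    if len(controls) < n_control_regions:
        raise ParameterError("background catalog yielded too few control regions")

    # the unit set per region is a fixed design; panels and traits are
    # resimulated per replicate
    base_panel = simulate_genotype_panel(
        catalog, n_samples, seed=seeds[-2], variants_per_gene=6
    )
    unit_rng = np.random.default_rng(seeds[-1])
    region_models = {
        reg.region_id: random_weight_models(base_panel, reg, n_units, unit_rng)
        for reg in [region] + controls
    }

    def region_pvalues(reg_id: str, panel, y: np.ndarray) -> np.ndarray:
        preds = [
            pred.values
            for m in region_models[reg_id]
            if not (pred := predict_expression(m, panel)).missing
        ]
        _, _, p = bulk_linear_association(y, np.column_stack(preds))
        return p

    fractions = []
    for rep in range(n_replicates):
        s_panel, s_trait = seeds[2 * rep : 2 * rep + 2]
        panel = simulate_genotype_panel(
            catalog, n_samples, seed=s_panel, variants_per_gene=6
        )
        y = np.random.default_rng(s_trait).standard_normal(n_samples)
        control_p = [region_pvalues(reg.region_id, panel, y) for reg in controls]
        threshold = permutation_threshold(control_p, percentile=percentile)
        cnv_p = region_pvalues(region.region_id, panel, y)
        fractions.append(float((cnv_p < threshold).mean()))
    return {
        "mean_pass_fraction": float(np.mean(fractions)),
        "per_replicate": fractions,
        "n_replicates": n_replicates,
    }


# --------------------------------------------------------------------------
# 2. pairwise-architecture recovery (variance-comparison tally)
# --------------------------------------------------------------------------
def pairwise_architecture_recovery(
    seed: int,
    *,
    n_blocks: int = 4,
    reps_per_block: int = 5,
    n_samples: int = 5000,
    n_train: int = 300,
    n_tissues: int = 3,
    n_cohorts: int = 3,
    effect_size: float = 0.1,
    n_controls: int = 10,
) -> dict:
    """Winner tallies and CNV-vs-control chi-square under a gene-pair
    trait, plus the null calibration of the same comparison.

    Models are elastic-net trained per block (training panel and the
    ``n_cohorts`` cohort panels resimulated each block); within a block
    trait noise is redrawn per replicate. Power and null arms share the
    trained models. The tally runs over cohort x tissue rows, as the
    published comparison does.
    """
    block_seeds = _seed_seq(seed, n_blocks)
    power_rows_best = []
    power_ps = []
    null_ps = []
    for b, bs in enumerate(block_seeds):
        sub_seeds = _seed_seq(bs, 5 + n_cohorts + 2 * reps_per_block * n_cohorts)
        catalog, region = generate_gene_catalog(200, CnvSpec(), seed=sub_seeds[0])
        controls = match_control_regions(region, catalog, max_regions=n_controls)
        regions = [region] + controls
        used_cat = catalog.subset([g for r in regions for g in r.member_gene_ids])

        train = simulate_genotype_panel(
            catalog, n_train, seed=sub_seeds[1], variants_per_gene=10
        )
        expr = simulate_expression_panel(
            train, used_cat, EqtlSpec(), n_tissues, seed=sub_seeds[2]
        )
        cohort_ids = [f"C{c + 1}" for c in range(n_cohorts)]
        cohorts = {
            cid: simulate_genotype_panel(
                catalog, n_samples, seed=sub_seeds[3 + c], variants_per_gene=10
            )
            for c, cid in enumerate(cohort_ids)
        }

        single_preds: dict[tuple[str, str, str], pd.DataFrame] = {}
        pair_preds: dict[tuple[str, str, str], pd.DataFrame] = {}
        for reg in regions:
            models = filter_models(
                train_region_models(
                    train, expr, catalog, reg, seed=sub_seeds[3 + n_cohorts], **_FAST_TRAIN
                )
            )
            for cid, cohort in cohorts.items():
                for t in expr.tissue_ids:
                    single_preds[(reg.region_id, cid, t)] = prediction_frame(
                        models, cohort, tissue_id=t, pairs=False
                    )
                    pair_preds[(reg.region_id, cid, t)] = prediction_frame(
                        models, cohort, tissue_id=t, pairs=True
                    )

        pair_rng = np.random.default_rng(sub_seeds[4 + n_cohorts])
        trait_seeds = sub_seeds[5 + n_cohorts :]
        seed_i = 0
        for rep in range(reps_per_block):
            targets = [
                region.member_gene_ids[i]
                for i in pair_rng.choice(len(region.member_gene_ids), 2, replace=False)
            ]
            for arm in ("power", "null"):
                es_spec = (
                    EffectSpec(
                        architecture="gene_pair",
                        target_gene_ids=targets,
                        effect_size=effect_size,
                    )
                    if arm == "power"
                    else EffectSpec(architecture="null")
                )
                phenos = {}
                for cid in cohort_ids:
                    phenos[cid] = simulate_trait(
                        cohorts[cid], expr.truth, es_spec, seed=trait_seeds[seed_i]
                    )
                    seed_i += 1
                cnv_rows = []
                control_rows = []
                for reg in regions:
                    singles = {
                        (cid, t): single_preds[(reg.region_id, cid, t)]
                        for cid in cohort_ids
                        for t in expr.tissue_ids
                    }
                    pairs = {
                        (cid, t): pair_preds[(reg.region_id, cid, t)]
                        for cid in cohort_ids
                        for t in expr.tissue_ids
                    }
                    rows = tally_best_models(singles, pairs, phenos, reg.region_id)
                    (cnv_rows if reg is region else control_rows).extend(rows)
                try:
                    _, p = compare_regions(cnv_rows, control_rows)
                except ParameterError:
                    # zero pairwise-best margin: no evidence of a difference
                    p = 1.0
                if arm == "power":
                    power_rows_best.extend(r.winner == "pairwise" for r in cnv_rows)
                    power_ps.append(p)
                else:
                    null_ps.append(p)
    return {
        "pairwise_best_fraction": float(np.mean(power_rows_best)),
        "chi2_power_fraction": float(np.mean([p < 0.05 for p in power_ps])),
        "null_calibration_fraction": float(np.mean([p > 0.01 for p in null_ps])),
        "n_replicates": len(power_ps),
        "n_rows": len(power_rows_best),
    }


# --------------------------------------------------------------------------
# 3. region-wide score recovery
# --------------------------------------------------------------------------
def regionwide_recovery(
    seed: int,
    *,
    n_replicates: int = 20,
    n_samples: int = 5000,
    n_train: int = 300,
    n_tissues: int = 3,
    effect_size: float = 0.02,
) -> dict:
    """Power of the region-wide rank score under a region-wide trait and
    its behaviour under the null."""
    seeds = _seed_seq(seed, 5 * n_replicates)
    power_p = []
    null_r = []
    for rep in range(n_replicates):
        s_cat, s_train, s_expr, s_cohort, s_trait = seeds[5 * rep : 5 * rep + 5]
        catalog, region = generate_gene_catalog(10, CnvSpec(), seed=s_cat)
        sub = catalog.subset(region.member_gene_ids)
        train = simulate_genotype_panel(catalog, n_train, seed=s_train, variants_per_gene=10)
        expr = simulate_expression_panel(train, sub, EqtlSpec(), n_tissues, seed=s_expr)
        cohort = simulate_genotype_panel(catalog, n_samples, seed=s_cohort, variants_per_gene=10)
        models = filter_models(
            train_region_models(
                train, expr, catalog, region, include_pairs=False,
                seed=s_expr, **_FAST_TRAIN,
            )
        )
        gene_ranks = {}
        for g in region.member_gene_ids:
            by_tissue = {
                m.tissue_id: pred.values
                for m in models
                if m.unit_id == g and not (pred := predict_expression(m, cohort)).missing
            }
            if by_tissue:
                gene_ranks[g] = per_gene_rank(by_tissue)
        scores = regionwide_score(gene_ranks, sample_ids=cohort.sample_ids)

        for arm in ("power", "null"):
            spec = (
                EffectSpec(
                    architecture="regionwide",
                    target_gene_ids=list(region.member_gene_ids),
                    effect_size=effect_size,
                )
                if arm == "power"
                else EffectSpec(architecture="null")
            )
            pheno = simulate_trait(
                cohort, expr.truth, spec, seed=s_trait + (arm == "null")
            )
            res = score_trait_association(scores, pheno)
            if arm == "power":
                power_p.append(res["pearson_p"])
            else:
                null_r.append(abs(res["pearson_r"]))
    return {
        "power_fraction": float(np.mean([p < 1e-4 for p in power_p])),
        "null_small_r_fraction": float(np.mean([r < 0.03 for r in null_r])),
        "n_replicates": n_replicates,
    }


# --------------------------------------------------------------------------
# 4. hub-gene over-representation
# --------------------------------------------------------------------------
def hub_overrepresentation(
    seed: int,
    *,
    n_replicates: int = 20,
    n_genes: int = 15,
    n_partners: int = 10,
    n_samples: int = 3000,
    n_controls: int = 20,
    effect_size: float = 0.03,
    k_sd: float = 2.5,
) -> dict:
    """A hub gene drives pairs with several partners; it should be
    flagged over-represented while null genes should not.

    The hub enters every pair-mediator term, so its variance share of
    the trait is k/(k+1) against 1/(k^2+k) per partner; at the default
    effect size and cohort size the hub's pairs sit far above the
    permutation threshold while partner spillover mostly sits below it.
    The hub is drawn from the more-heritable half of the region's genes
    (a gene with usable expression models, as a real prioritization
    target would be); partners are drawn from the remaining genes.
    """
    catalog, region = generate_gene_catalog(
        500, CnvSpec(n_genes=n_genes, length_bp=1_200_000), seed=seed
    )
    controls = match_control_regions(region, catalog, max_regions=n_controls)
    regions = [region] + controls
    used_cat = catalog.subset([g for r in regions for g in r.member_gene_ids])
    seeds = _seed_seq(seed + 1, 4 * n_replicates)
    hub_flags = []
    null_flags = []
    for rep in range(n_replicates):
        s_panel, s_expr, s_trait, s_pick = seeds[4 * rep : 4 * rep + 4]
        panel = simulate_genotype_panel(catalog, n_samples, seed=s_panel, variants_per_gene=8)
        expr = simulate_expression_panel(panel, used_cat, EqtlSpec(), 1, seed=s_expr)
        rng = np.random.default_rng(s_trait)
        pick = np.random.default_rng(s_pick)
        members = list(region.member_gene_ids)
        h2 = expr.truth.h2_by_gene
        eligible = sorted(members, key=h2.get, reverse=True)[: len(members) // 2]
        hub = eligible[pick.integers(len(eligible))]
        partners = [g for g in members if g != hub]
        partners = [partners[i] for i in pick.choice(len(partners), n_partners, replace=False)]
        mediator = np.sum(
            [
                inverse_normal_transform(
                    expr.truth.total_expression(panel, hub, "T1", rng)
                    + expr.truth.total_expression(panel, p, "T1", rng)
                )
                for p in partners
            ],
            axis=0,
        )
        y = np.sqrt(effect_size) * standardize(mediator) + np.sqrt(
            1 - effect_size
        ) * rng.standard_normal(n_samples)
        pheno = PhenotypeTable(
            sample_ids=list(panel.sample_ids),
            trait_name="hub_trait",
            trait_type="quantitative",
            values=y,
        )

        def region_pair_pvalues(reg: RegionDefinition) -> dict[tuple[str, str], float]:
            models = oracle_weight_models(
                expr.truth, panel, reg.member_gene_ids, ["T1"],
                catalog=used_cat, include_pairs=True,
            )
            out = {}
            for m in models:
                if not m.is_pair:
                    continue
                rec = associate_tissue(predict_expression(m, panel), pheno)
                if rec is not None:
                    ga, _, gb = m.unit_id.partition("|")
                    out[(ga, gb)] = rec.p
            return out

        control_p = [list(region_pair_pvalues(r).values()) for r in controls]
        threshold = permutation_threshold(control_p)
        cnv_p = region_pair_pvalues(region)
        significant = [pair for pair, p in cnv_p.items() if p < threshold]
        counts = count_pair_memberships(significant, region, used_cat)
        flagged = flag_overrepresented(counts, k_sd=k_sd)
        hub_flags.append(hub in flagged)
        null_genes = [g for g in members if g != hub and g not in partners]
        null_flags.extend(g in flagged for g in null_genes)
    return {
        "hub_flag_rate": float(np.mean(hub_flags)),
        "null_gene_flag_rate": float(np.mean(null_flags)),
        "n_replicates": n_replicates,
    }


# --------------------------------------------------------------------------
# 5. elastic-net oracle: support recovery and the in-between property
# --------------------------------------------------------------------------
def elasticnet_oracle(
    seed: int,
    *,
    n_recovery_replicates: int = 50,
    n_train: int = 500,
    n_inbetween_genes: int = 15,
    n_tissues: int = 3,
) -> dict:
    """(a) With one causal cis SNP at h2=0.5, the causal SNP should sit
    in the trained model's support; (b) per pair, the pair model's cv R2
    (median across tissues) should lie between its two constituents'."""
    seeds = _seed_seq(seed, 3 * n_recovery_replicates + 4)
    recovered = []
    for rep in range(n_recovery_replicates):
        s_cat, s_panel, s_expr = seeds[3 * rep : 3 * rep + 3]
        catalog, region = generate_gene_catalog(2, CnvSpec(n_genes=2), seed=s_cat)
        gene = region.member_gene_ids[0]
        sub = catalog.subset([gene])
        panel = simulate_genotype_panel(catalog, n_train, seed=s_panel, variants_per_gene=10)
        expr = simulate_expression_panel(
            panel, sub, EqtlSpec(n_causal_per_gene=1, h2_cis=0.5), 1, seed=s_expr
        )
        one_gene_region = RegionDefinition(
            region_id=region.region_id,
            chrom=region.chrom,
            start=region.start,
            end=region.end,
            member_gene_ids=[gene],
        )
        models = train_region_models(
            panel, expr, catalog, one_gene_region,
            include_pairs=False, seed=s_expr, **_FAST_TRAIN,
        )
        causal = expr.truth.causal_by_gene[gene][0]
        recovered.append(causal in set(models[0].weights["variant_id"]))

    s_cat, s_panel, s_expr, s_train = seeds[-4:]
    catalog, region = generate_gene_catalog(
        10, CnvSpec(n_genes=n_inbetween_genes, length_bp=1_200_000), seed=s_cat
    )
    sub = catalog.subset(region.member_gene_ids)
    panel = simulate_genotype_panel(catalog, 300, seed=s_panel, variants_per_gene=10)
    expr = simulate_expression_panel(panel, sub, EqtlSpec(), n_tissues, seed=s_expr)
    models = train_region_models(
        panel, expr, catalog, region, seed=s_train, **_FAST_TRAIN
    )
    by_unit: dict[str, list[float]] = {}
    for m in models:
        by_unit.setdefault(m.unit_id, []).append(m.cv_performance_r2)
    medians = {u: float(np.median(v)) for u, v in by_unit.items()}
    between = []
    for ga, gb in enumerate_pairs(region, catalog):
        uid = pair_unit_id(ga, gb, catalog)
        if uid not in medians or ga not in medians or gb not in medians:
            continue
        lo, hi = sorted((medians[ga], medians[gb]))
        between.append(lo <= medians[uid] <= hi)
    # sign test against the 1/3 chance of landing between two exchangeable draws
    test = stats.binomtest(int(np.sum(between)), len(between), p=1.0 / 3.0,
                           alternative="greater")
    return {
        "support_recovery_rate": float(np.mean(recovered)),
        "inbetween_fraction": float(np.mean(between)),
        "inbetween_sign_p": float(test.pvalue),
        "n_pairs": len(between),
        "n_recovery_replicates": n_recovery_replicates,
    }


# --------------------------------------------------------------------------
# 6/7. summary-level vs individual-level internal consistency
# --------------------------------------------------------------------------
def summary_individual_consistency(
    seed: int,
    *,
    n_genes: int = 10,
    n_samples: int = 3000,
    n_train: int = 300,
    n_reference: int = 500,
    n_tissues: int = 3,
    effect_size: float = 0.05,
) -> dict:
    """Tissue-level z and cross-tissue -log10 p agreement between the
    individual-level and summary-level association routes on one cohort."""
    seeds = _seed_seq(seed, 6)
    catalog, region = generate_gene_catalog(
        5, CnvSpec(n_genes=n_genes, length_bp=800_000), seed=seeds[0]
    )
    sub = catalog.subset(region.member_gene_ids)
    train = simulate_genotype_panel(catalog, n_train, seed=seeds[1], variants_per_gene=10)
    expr = simulate_expression_panel(train, sub, EqtlSpec(), n_tissues, seed=seeds[2])
    cohort = simulate_genotype_panel(catalog, n_samples, seed=seeds[3], variants_per_gene=10)
    reference = simulate_genotype_panel(catalog, n_reference, seed=seeds[4], variants_per_gene=10)
    models = filter_models(
        train_region_models(train, expr, catalog, region, seed=seeds[5], **_FAST_TRAIN)
    )
    spec = EffectSpec(
        architecture="single_gene",
        target_gene_ids=[region.member_gene_ids[0]],
        effect_size=effect_size,
    )
    pheno = simulate_trait(cohort, expr.truth, spec, seed=seeds[5] + 1)
    sumstats = compute_gwas_summary(cohort, pheno)

    z_ind, z_sum = [], []
    units = sorted({m.unit_id for m in models})
    cross_pairs = []
    for uid in units:
        unit_models = [m for m in models if m.unit_id == uid]
        preds = {}
        z_by_tissue = {}
        ref_preds = {}
        for m in unit_models:
            pred = predict_expression(m, cohort)
            rec = associate_tissue(pred, pheno)
            srec = spredixcan_z(m, sumstats, reference)
            if rec is None or srec is None:
                continue
            z_ind.append(rec.effect / rec.se)
            z_sum.append(srec.effect)
            preds[m.tissue_id] = pred.values
            z_by_tissue[m.tissue_id] = srec.effect
            rp = predict_expression(m, reference)
            if not rp.missing:
                ref_preds[m.tissue_id] = rp.values
        if len(preds) < 2 or set(ref_preds) != set(z_by_tissue):
            continue
        ind_rec = combine_tissues_individual(preds, pheno, unit_id=uid)
        try:
            corr = tissue_correlation(ref_preds)
            sum_rec = combine_tissues_summary(z_by_tissue, corr, unit_id=uid)
        except (ParameterError, ValueError):
            continue
        if ind_rec is not None:
            cross_pairs.append((-np.log10(ind_rec.p), -np.log10(sum_rec.p)))

    z_r = float(np.corrcoef(z_ind, z_sum)[0, 1])
    cp = np.asarray(cross_pairs)
    cross_r = float(np.corrcoef(cp[:, 0], cp[:, 1])[0, 1]) if len(cp) > 2 else float("nan")
    return {
        "tissue_z_pearson_r": z_r,
        "cross_tissue_logp_pearson_r": cross_r,
        "n_tissue_units": len(z_ind),
        "n_cross_units": len(cp),
    }
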