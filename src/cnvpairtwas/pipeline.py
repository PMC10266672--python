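"""End-to-end pipeline runner: simulate -> match-controls -> train ->
associate -> threshold -> variance -> pairs -> regionscore.

The runner is deliberately file-centric: every stage writes its outputs
as TSV into the run directory and later stages reload them on demand, so
any contiguous subset of stages can be rerun against prebuilt inputs.
Rerunning with an identical config and seed reproduces identical output
files. Each stochastic stage consumes a seed derived deterministically
from the master seed and the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    associate_tissue,
    combine_tissues_individual,
    combine_tissues_summary,
    meta_analyze,
    permutation_threshold,
    prediction_frame,
    predict_expression,
    records_to_frame,
    spredixcan_z,
    tissue_correlation,
)
from .catalog import GeneCatalog, RegionDefinition, read_regions_tsv, write_regions_tsv
from .exceptions import DependencyError, ParameterError
from .expression_models import (
    WeightModel,
    filter_models,
    read_weight_models,
    train_region_models,
    write_weight_models,
)
from .genotypes import GenotypePanel
from .pair_composition import (
    annotate_single_gene_status,
    count_pair_memberships,
    flag_overrepresented,
)
from .phenotypes import PhenotypeTable, SummaryStats
from .region_matching import match_control_regions
from .regionwide_score import (
    decile_summary,
    per_gene_rank,
    regionwide_score,
    score_trait_association,
)
from .synthetic import (
    CnvSpec,
    EffectSpec,
    EqtlSpec,
    compute_gwas_summary,
    generate_gene_catalog,
    simulate_expression_panel,
    simulate_genotype_panel,
    simulate_trait,
)
from .variance_comparison import compare_regions, tally_best_models, tally_frame

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "match-controls",
    "train",
    "associate",
    "threshold",
    "variance",
    "pairs",
    "regionscore",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (master_seed ^ zlib.crc32(stage.encode())) % (2**31)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
@dataclass
class CohortConfig:
    cohort_id: str = "C1"
    n_samples: int = 2000
    architecture: str = "gene_pair"
    target_genes: list[str] | str = "auto"
    effect_size: float = 0.1
    trait_type: str = "quantitative"
    prevalence: float = 0.3
    trait_name: str = "trait"


@dataclass
class PipelineConfig:
    """Demo-scale defaults: an 8-gene CNV among 200 background genes,
    two cohorts of 2000, three tissues."""

    seed: int = 0
    n_background_genes: int = 200
    cnv: CnvSpec = field(default_factory=CnvSpec)
    # genotypes
    variants_per_gene: int = 8
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_rho: float = 0.3
    # expression training panel
    n_tissues: int = 3
    n_train_samples: int = 300
    eqtl: EqtlSpec = field(default_factory=EqtlSpec)
    # cohorts
    cohorts: list[CohortConfig] = field(
        default_factory=lambda: [
            CohortConfig(cohort_id="C1"),
            CohortConfig(cohort_id="C2"),
        ]
    )
    # model training
    alpha: float = 0.5
    n_folds: int = 10
    n_alphas: int = 20
    snp_allowlist: list[str] | None = None
    r2_min: float = 0.01
    p_max: float = 0.05
    # control matching
    length_bounds: tuple[float, float] = (0.8, 1.2)
    ratio_min_fraction: float = 0.8
    max_control_regions: int = 4
    exclusions: list[dict] = field(default_factory=list)
    # association
    association_level: str = "individual"  # or "summary"
    condition_limit: float = 30.0
    percentile: float = 5.0
    # pair composition
    k_sd: float = 2.5
    # io
    write_genotypes: bool = True

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        if "cnv" in raw and isinstance(raw["cnv"], dict):
            raw["cnv"] = CnvSpec(**raw["cnv"])
        if "eqtl" in raw and isinstance(raw["eqtl"], dict):
            eq = dict(raw["eqtl"])
            if isinstance(eq.get("h2_cis"), list):
                eq["h2_cis"] = tuple(eq["h2_cis"])
            raw["eqtl"] = EqtlSpec(**eq)
        if "cohorts" in raw:
            raw["cohorts"] = [
                c if isinstance(c, CohortConfig) else CohortConfig(**c)
                for c in raw["cohorts"]
            ]
        for key in ("maf_range", "length_bounds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# run state with lazy loading from the run directory
# --------------------------------------------------------------------------
class _ExpressionStore:
    """Minimal expression container reloadable from TSV."""

    def __init__(self, expression: dict[tuple[str, str], np.ndarray]):
        self.expression = expression

    def tissues_for(self, gene_id: str) -> list[str]:
        return sorted(t for (t, g) in self.expression if g == gene_id)

    def to_tsv(self, path: Path) -> None:
        rows = []
        for (t, g), v in sorted(self.expression.items()):
            for i, x in enumerate(v):
                rows.append((t, g, i, x))
        pd.DataFrame(rows, columns=["tissue_id", "gene_id", "sample_idx", "value"]).to_csv(
            path, sep="\t", index=False, float_format="%.8g"
        )

    @classmethod
    def from_tsv(cls, path: Path) -> "_ExpressionStore":
        df = pd.read_csv(path, sep="\t")
        expression = {
            (t, g): sub.sort_values("sample_idx")["value"].to_numpy()
            for (t, g), sub in df.groupby(["tissue_id", "gene_id"])
        }
        return cls(expression)


class PipelineState:
    """In-memory artifacts plus lazy reload from the output directory."""

    def __init__(self, config: PipelineConfig, out_dir: Path):
        self.config = config
        self.out = Path(out_dir)
        self.catalog: GeneCatalog | None = None
        self.region: RegionDefinition | None = None
        self.controls: list[RegionDefinition] | None = None
        self.train_panel: GenotypePanel | None = None
        self.expression = None  # ExpressionPanel or _ExpressionStore
        self.cohort_panels: dict[str, GenotypePanel] = {}
        self.phenotypes: dict[str, PhenotypeTable] = {}
        self.sumstats: dict[str, SummaryStats] = {}
        self.models: list[WeightModel] | None = None
        self.associations: pd.DataFrame | None = None
        self.thresholds: pd.DataFrame | None = None

    # -- dependency access with reload fallbacks -------------------------
    def _require(self, path: str, stage: str) -> Path:
        p = self.out / path
        if not p.exists():
            raise DependencyError(
                f"stage '{stage}' needs missing artifact {path}; run its upstream stages first"
            )
        return p

    def need_catalog(self, stage: str) -> GeneCatalog:
        if self.catalog is None:
            self.catalog = GeneCatalog.from_tsv(self._require("catalog.tsv", stage))
        return self.catalog

    def need_regions(self, stage: str) -> tuple[RegionDefinition, list[RegionDefinition]]:
        if self.region is None:
            regions = read_regions_tsv(
                self._require("regions.tsv", stage),
                self._require("region_members.tsv", stage),
            )
            cnv = [r for r in regions if r.region_id == "CNV"]
            if not cnv:
                raise DependencyError(f"stage '{stage}': no CNV region on disk")
            self.region = cnv[0]
            ctrl = [r for r in regions if r.region_id != "CNV"]
            self.controls = ctrl if ctrl else self.controls
        if self.controls is None:
            self.controls = []
        return self.region, self.controls

    def need_train_panel(self, stage: str) -> GenotypePanel:
        if self.train_panel is None:
            self.train_panel = GenotypePanel.from_dosage_tsv(
                self._require("train_panel.dosage.tsv", stage)
            )
        return self.train_panel

    def need_expression(self, stage: str):
        if self.expression is None:
            self.expression = _ExpressionStore.from_tsv(
                self._require("expression.tsv", stage)
            )
        return self.expression

    def need_cohort(self, cohort_id: str, stage: str) -> GenotypePanel:
        if cohort_id not in self.cohort_panels:
            self.cohort_panels[cohort_id] = GenotypePanel.from_dosage_tsv(
                self._require(f"{cohort_id}.dosage.tsv", stage)
            )
        return self.cohort_panels[cohort_id]

    def need_phenotype(self, cc: CohortConfig, stage: str) -> PhenotypeTable:
        if cc.cohort_id not in self.phenotypes:
            self.phenotypes[cc.cohort_id] = PhenotypeTable.from_tsv(
                self._require(f"{cc.cohort_id}.pheno.tsv", stage),
                trait_name=cc.trait_name,
                trait_type=cc.trait_type,
            )
        return self.phenotypes[cc.cohort_id]

    def need_sumstats(self, cohort_id: str, stage: str) -> SummaryStats:
        if cohort_id not in self.sumstats:
            self.sumstats[cohort_id] = SummaryStats.from_tsv(
                self._require(f"{cohort_id}.sumstats.tsv", stage)
            )
        return self.sumstats[cohort_id]

    def need_models(self, stage: str) -> list[WeightModel]:
        if self.models is None:
            self.models = read_weight_models(
                self._require("weights.tsv", stage), self._require("extra.tsv", stage)
            )
        return self.models

    def need_associations(self, stage: str) -> pd.DataFrame:
        if self.associations is None:
            self.associations = pd.read_csv(
                self._require("associations.tsv", stage), sep="\t"
            )
        return self.associations

    def need_thresholds(self, stage: str) -> pd.DataFrame:
        if self.thresholds is None:
            self.thresholds = pd.read_csv(
                self._require("thresholds.tsv", stage), sep="\t"
            )
        return self.thresholds

    def filtered_models(self, stage: str) -> list[WeightModel]:
        cfg = self.config
        return filter_models(self.need_models(stage), cfg.r2_min, cfg.p_max)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------
def _resolve_targets(cc: CohortConfig, region: RegionDefinition) -> list[str]:
    if cc.target_genes != "auto":
        return list(cc.target_genes)
    if cc.architecture == "single_gene":
        return region.member_gene_ids[:1]
    if cc.architecture == "gene_pair":
        return region.member_gene_ids[:2]
    if cc.architecture == "regionwide":
        return list(region.member_gene_ids)
    return []


def _stage_simulate(state: PipelineState) -> None:
    cfg = state.config
    seed = stage_seed(cfg.seed, "simulate")
    catalog, region = generate_gene_catalog(
        cfg.n_background_genes, cfg.cnv, seed=seed
    )
    state.catalog, state.region = catalog, region
    catalog.to_tsv(state.out / "catalog.tsv")

    train_panel = simulate_genotype_panel(
        catalog,
        cfg.n_train_samples,
        maf_range=cfg.maf_range,
        ld_block_size=cfg.ld_block_size,
        ld_rho=cfg.ld_rho,
        seed=stage_seed(cfg.seed, "simulate/train_panel"),
        variants_per_gene=cfg.variants_per_gene,
        sample_prefix="TP",
    )
    state.train_panel = train_panel
    expr = simulate_expression_panel(
        train_panel,
        catalog,
        cfg.eqtl,
        cfg.n_tissues,
        seed=stage_seed(cfg.seed, "simulate/expression"),
    )
    state.expression = expr
    _ExpressionStore(expr.expression).to_tsv(state.out / "expression.tsv")

    for c, cc in enumerate(cfg.cohorts):
        panel = simulate_genotype_panel(
            catalog,
            cc.n_samples,
            maf_range=cfg.maf_range,
            ld_block_size=cfg.ld_block_size,
            ld_rho=cfg.ld_rho,
            seed=stage_seed(cfg.seed, f"simulate/cohort/{cc.cohort_id}"),
            variants_per_gene=cfg.variants_per_gene,
            sample_prefix=f"{cc.cohort_id}_",
        )
        spec = EffectSpec(
            architecture=cc.architecture,
            target_gene_ids=_resolve_targets(cc, region),
            effect_size=cc.effect_size,
            trait_type=cc.trait_type,
            prevalence=cc.prevalence,
            trait_name=cc.trait_name,
        )
        pheno = simulate_trait(
            panel, expr.truth, spec, seed=stage_seed(cfg.seed, f"simulate/trait/{cc.cohort_id}")
        )
        sumstats = compute_gwas_summary(panel, pheno)
        state.cohort_panels[cc.cohort_id] = panel
        state.phenotypes[cc.cohort_id] = pheno
        state.sumstats[cc.cohort_id] = sumstats
        pheno.to_tsv(state.out / f"{cc.cohort_id}.pheno.tsv")
        sumstats.to_tsv(state.out / f"{cc.cohort_id}.sumstats.tsv")
        if cfg.write_genotypes:
            panel.to_dosage_tsv(state.out / f"{cc.cohort_id}.dosage.tsv")
    if cfg.write_genotypes:
        train_panel.to_dosage_tsv(state.out / "train_panel.dosage.tsv")
    logger.info("simulate: %d genes, %d cohorts", len(catalog), len(cfg.cohorts))


def _stage_match_controls(state: PipelineState) -> None:
    cfg = state.config
    catalog = state.need_catalog("match-controls")
    if state.region is None:
        state.need_regions("match-controls")
    exclusions = [
        RegionDefinition(
            region_id=e.get("region_id", f"EXCL_{i}"),
            chrom=e["chrom"],
            start=int(e["start"]),
            end=int(e["end"]),
            member_gene_ids=["_"],
        )
        for i, e in enumerate(cfg.exclusions)
    ]
    controls = match_control_regions(
        state.region,
        catalog,
        length_bounds=cfg.length_bounds,
        ratio_min_fraction=cfg.ratio_min_fraction,
        exclusions=exclusions,
        max_regions=cfg.max_control_regions,
    )
    state.controls = controls
    write_regions_tsv(
        [state.region] + controls,
        state.out / "regions.tsv",
        state.out / "region_members.tsv",
    )
    logger.info("match-controls: %d control regions", len(controls))


def _stage_train(state: PipelineState) -> None:
    cfg = state.config
    catalog = state.need_catalog("train")
    region, controls = state.need_regions("train")
    panel = state.train_panel or state.need_train_panel("train")
    expr = state.need_expression("train")
    models: list[WeightModel] = []
    for reg in [region] + list(controls):
        models.extend(
            train_region_models(
                panel,
                expr,
                catalog,
                reg,
                snp_allowlist=cfg.snp_allowlist,
                alpha=cfg.alpha,
                n_folds=cfg.n_folds,
                seed=stage_seed(cfg.seed, "train"),
                n_alphas=cfg.n_alphas,
            )
        )
    state.models = models
    write_weight_models(models, state.out / "weights.tsv", state.out / "extra.tsv")
    n_empty = sum(m.is_empty for m in models)
    logger.info("train: %d models (%d empty)", len(models), n_empty)


def _region_of_unit(unit_id: str, regions: list[RegionDefinition]) -> str | None:
    genes = set(unit_id.split("|"))
    for reg in regions:
        if genes <= set(reg.member_gene_ids):
            return reg.region_id
    return None


def _stage_associate(state: PipelineState) -> None:
    cfg = state.config
    region, controls = state.need_regions("associate")
    regions = [region] + list(controls)
    models = state.filtered_models("associate")
    by_unit: dict[str, list[WeightModel]] = {}
    for m in models:
        if not m.is_empty:
            by_unit.setdefault(m.unit_id, []).append(m)

    records = []
    cross_by_unit: dict[str, list] = {}
    ns: dict[str, float] = {}
    for cc in cfg.cohorts:
        panel = state.cohort_panels.get(cc.cohort_id) or state.need_cohort(
            cc.cohort_id, "associate"
        )
        pheno = state.need_phenotype(cc, "associate")
        ns[cc.cohort_id] = pheno.n
        if cfg.association_level == "summary":
            sumstats = state.need_sumstats(cc.cohort_id, "associate")
            reference = state.train_panel or state.need_train_panel("associate")
        for uid, unit_models in sorted(by_unit.items()):
            preds = {}
            z_by_tissue = {}
            ref_preds = {}
            for m in unit_models:
                if cfg.association_level == "summary":
                    srec = spredixcan_z(
                        m, sumstats, reference, trait=cc.trait_name, cohort_id=cc.cohort_id
                    )
                    if srec is not None:
                        records.append(srec)
                        z_by_tissue[m.tissue_id] = srec.effect
                        rp = predict_expression(m, reference)
                        if not rp.missing:
                            ref_preds[m.tissue_id] = rp.values
                else:
                    pred = predict_expression(m, panel)
                    rec = associate_tissue(pred, pheno, cohort_id=cc.cohort_id)
                    if rec is not None:
                        records.append(rec)
                        preds[m.tissue_id] = pred.values
            if cfg.association_level == "summary":
                if not z_by_tissue or set(ref_preds) != set(z_by_tissue):
                    continue
                if len(z_by_tissue) == 1:
                    (only_z,) = z_by_tissue.values()
                    cross = records[-1]
                else:
                    cross = combine_tissues_summary(
                        z_by_tissue,
                        tissue_correlation(ref_preds),
                        unit_id=uid,
                        trait=cc.trait_name,
                        cohort_id=cc.cohort_id,
                        condition_limit=cfg.condition_limit,
                    )
                    records.append(cross)
            else:
                if not preds:
                    continue
                cross = combine_tissues_individual(
                    preds,
                    pheno,
                    unit_id=uid,
                    cohort_id=cc.cohort_id,
                    condition_limit=cfg.condition_limit,
                )
                if cross is None:
                    continue
                records.append(cross)
            cross_by_unit.setdefault(uid, []).append((cc.cohort_id, cross))

    for uid, pairs in sorted(cross_by_unit.items()):
        recs = [r for _, r in pairs]
        n_list = [ns[cid] for cid, _ in pairs]
        records.append(meta_analyze(recs, n_list))

    frame = records_to_frame(records)
    frame["region"] = frame["unit_id"].map(lambda u: _region_of_unit(u, regions))
    frame.to_csv(state.out / "associations.tsv", sep="\t", index=False, float_format="%.8g")
    state.associations = frame
    logger.info("associate: %d records", len(frame))


def _stage_threshold(state: PipelineState) -> None:
    cfg = state.config
    region, controls = state.need_regions("threshold")
    assoc = state.need_associations("threshold")
    meta = assoc[assoc["level"] == "meta"]
    rows = []
    trait = meta["trait"].iloc[0] if len(meta) else "trait"
    for unit_class in ("single", "pair"):
        control_p = []
        for reg in controls:
            sub = meta[
                (meta["region"] == reg.region_id) & (meta["unit_class"] == unit_class)
            ]
            if len(sub):
                control_p.append(sub["p"].to_numpy())
        if not control_p:
            logger.warning("threshold: no control p-values for class %s", unit_class)
            continue
        thr = permutation_threshold(control_p, percentile=cfg.percentile)
        rows.append((trait, region.region_id, unit_class, thr))
    thresholds = pd.DataFrame(
        rows, columns=["trait", "region", "unit_class", "threshold"]
    )
    thresholds.to_csv(state.out / "thresholds.tsv", sep="\t", index=False, float_format="%.8g")
    state.thresholds = thresholds
    logger.info("threshold: %s", thresholds.to_dict("records"))


def _stage_variance(state: PipelineState) -> None:
    cfg = state.config
    region, controls = state.need_regions("variance")
    models = state.filtered_models("variance")
    member_map = {
        reg.region_id: set(reg.member_gene_ids) for reg in [region] + list(controls)
    }
    cnv_rows = []
    control_rows = []
    phenos = {
        cc.cohort_id: state.need_phenotype(cc, "variance") for cc in cfg.cohorts
    }
    tissues = sorted({m.tissue_id for m in models})
    for reg_id, genes in member_map.items():
        reg_models = [m for m in models if set(m.unit_id.split("|")) <= genes]
        singles = {}
        pairs = {}
        for cc in cfg.cohorts:
            panel = state.cohort_panels.get(cc.cohort_id) or state.need_cohort(
                cc.cohort_id, "variance"
            )
            for t in tissues:
                singles[(cc.cohort_id, t)] = prediction_frame(
                    reg_models, panel, tissue_id=t, pairs=False
                )
                pairs[(cc.cohort_id, t)] = prediction_frame(
                    reg_models, panel, tissue_id=t, pairs=True
                )
        rows = tally_best_models(singles, pairs, phenos, reg_id)
        (cnv_rows if reg_id == region.region_id else control_rows).extend(rows)

    tally = tally_frame(cnv_rows + control_rows)
    tally.to_csv(state.out / "tally.tsv", sep="\t", index=False, float_format="%.6g")
    trait = cfg.cohorts[0].trait_name if cfg.cohorts else "trait"
    try:
        statistic, p = compare_regions(cnv_rows, control_rows)
    except ParameterError as exc:
        logger.warning("variance: chi-square undefined (%s)", exc)
        statistic, p = float("nan"), float("nan")
    comparison = pd.DataFrame(
        [
            {
                "region": region.region_id,
                "trait": trait,
                "cnv_pairwise_best": sum(r.winner == "pairwise" for r in cnv_rows),
                "cnv_rows": len(cnv_rows),
                "control_pairwise_best": sum(
                    r.winner == "pairwise" for r in control_rows
                ),
                "control_rows": len(control_rows),
                "chi2": statistic,
                "p": p,
            }
        ]
    )
    comparison.to_csv(state.out / "comparison.tsv", sep="\t", index=False, float_format="%.8g")
    logger.info("variance: %d CNV rows, %d control rows", len(cnv_rows), len(control_rows))


def _stage_pairs(state: PipelineState) -> None:
    cfg = state.config
    region, _ = state.need_regions("pairs")
    catalog = state.need_catalog("pairs")
    assoc = state.need_associations("pairs")
    thresholds = state.need_thresholds("pairs")
    meta = assoc[(assoc["level"] == "meta") & (assoc["region"] == region.region_id)]

    def class_threshold(unit_class: str) -> float | None:
        sub = thresholds[thresholds["unit_class"] == unit_class]
        return float(sub["threshold"].iloc[0]) if len(sub) else None

    pair_thr = class_threshold("pair")
    single_thr = class_threshold("single")
    pair_meta = meta[meta["unit_class"] == "pair"]
    significant = [
        tuple(uid.split("|"))
        for uid, p in zip(pair_meta["unit_id"], pair_meta["p"])
        if pair_thr is not None and p < pair_thr
    ]
    counts = count_pair_memberships(significant, region, catalog)
    flag_overrepresented(counts, k_sd=cfg.k_sd)
    single_meta = meta[meta["unit_class"] == "single"]
    single_p = dict(zip(single_meta["unit_id"], single_meta["p"]))
    if single_thr is not None:
        annotate_single_gene_status(counts, single_p, single_thr)
    counts.table.to_csv(
        state.out / "pair_counts.tsv", sep="\t", index=False, float_format="%.6g"
    )
    logger.info("pairs: %d significant pairs", len(significant))


def _stage_regionscore(state: PipelineState) -> None:
    cfg = state.config
    region, _ = state.need_regions("regionscore")
    models = [
        m
        for m in state.filtered_models("regionscore")
        if not m.is_pair and m.unit_id in set(region.member_gene_ids)
    ]
    assoc_rows = []
    for cc in cfg.cohorts:
        panel = state.cohort_panels.get(cc.cohort_id) or state.need_cohort(
            cc.cohort_id, "regionscore"
        )
        pheno = state.need_phenotype(cc, "regionscore")
        gene_ranks = {}
        for g in region.member_gene_ids:
            by_tissue = {}
            for m in models:
                if m.unit_id != g:
                    continue
                pred = predict_expression(m, panel)
                if not pred.missing:
                    by_tissue[m.tissue_id] = pred.values
            if by_tissue:
                gene_ranks[g] = per_gene_rank(by_tissue)
            else:
                logger.info("regionscore: gene %s has no retained model", g)
        scores = regionwide_score(gene_ranks, sample_ids=panel.sample_ids)
        scores.to_frame().to_csv(
            state.out / f"scores_{cc.cohort_id}.tsv", sep="\t", index=False,
            float_format="%.8g",
        )
        stats_out = score_trait_association(scores, pheno)
        for k, v in stats_out.items():
            assoc_rows.append((cc.trait_name, cc.cohort_id, k, v))
        decile_summary(scores, pheno).to_csv(
            state.out / f"deciles_{cc.cohort_id}.tsv", sep="\t", index=False,
            float_format="%.8g",
        )
    pd.DataFrame(
        assoc_rows, columns=["trait", "cohort", "statistic", "value"]
    ).to_csv(state.out / "score_association.tsv", sep="\t", index=False, float_format="%.8g")
    logger.info("regionscore: done")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "match-controls": _stage_match_controls,
    "train": _stage_train,
    "associate": _stage_associate,
    "threshold": _stage_threshold,
    "variance": _stage_variance,
    "pairs": _stage_pairs,
    "regionscore": _stage_regionscore,
}


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    stages: list[str] | None = None,
) -> PipelineState:
    """Run the requested stages (default: all, in order) into ``out_dir``.

    Stage subsets reuse on-disk artifacts from earlier runs; a missing
    upstream artifact raises :class:`DependencyError` naming the stage.
    """
    wanted = list(stages) if stages else list(STAGES)
    unknown = [s for s in wanted if s not in STAGES]
    if unknown:
        raise ParameterError(f"unknown stages: {unknown}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = PipelineState(config, out)
    for stage in STAGES:
        if stage in wanted:
            logger.info("running stage %s", stage)
            _STAGE_FUNCS[stage](state)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "stages": wanted,
        "config": config.to_dict(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return state
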