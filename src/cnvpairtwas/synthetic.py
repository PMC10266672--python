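"""Synthetic genotype / expression / trait generator.

This module builds the fully-specified toy genome on which the rest of
the pipeline is exercised:

* a gene catalog with one designated multi-gene CNV region plus background
  genes laid out comparably, so that control-region matching has material
  to work with;
* LD-structured genotype dosage panels (block compound-symmetric latent
  Gaussian copula, thresholded per haplotype at the target allele
  frequency, two haplotypes summed);
* multi-tissue expression with a sparse cis-eQTL architecture: per gene a
  few causal cis variants, per-gene cis heritability, and a shared effect
  component that induces cross-tissue correlation;
* traits mediated through expression under four architectures (null,
  single gene, gene pair, region-wide), with binary traits generated by a
  liability-threshold model;
* per-variant GWAS summary statistics (linear model with covariates, for
  both quantitative and 0/1-coded binary traits).

Every function is a pure function of its arguments including ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from ._stats import bulk_linear_association, standardize
from .catalog import BIOTYPES, GeneCatalog, RegionDefinition
from .exceptions import AlignmentError, ParameterError
from .genotypes import GenotypePanel
from .phenotypes import PhenotypeTable, SummaryStats
from .transforms import inverse_normal_transform

NONCODING_BIOTYPES = tuple(b for b in BIOTYPES if b != "protein_coding")


# --------------------------------------------------------------------------
# parameter bundles
# --------------------------------------------------------------------------
@dataclass
class CnvSpec:
    """Shape of the designated CNV region."""

    n_genes: int = 8
    coding_fraction: float = 0.75
    length_bp: int = 600_000

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ParameterError("a CNV region needs at least 2 genes")
        if not 0.0 <= self.coding_fraction <= 1.0:
            raise ParameterError("coding_fraction must lie in [0, 1]")
        if self.length_bp <= 0:
            raise ParameterError("length_bp must be positive")


@dataclass
class EqtlSpec:
    """cis-eQTL architecture of the expression panel.

    ``h2_cis`` may be a scalar (every gene identical) or a (low, high)
    range from which a per-gene cis heritability is drawn — gene-to-gene
    variation in predictability is the realistic default.
    """

    n_causal_per_gene: int = 3
    h2_cis: float | tuple[float, float] = (0.1, 0.8)
    cross_tissue_sharing: float = 0.7

    def __post_init__(self) -> None:
        lo, hi = self.h2_bounds()
        if not (0.0 <= lo <= hi <= 1.0):
            raise ParameterError("h2_cis must lie in [0, 1]")
        if not 0.0 <= self.cross_tissue_sharing <= 1.0:
            raise ParameterError("cross_tissue_sharing must lie in [0, 1]")
        if self.n_causal_per_gene < 1:
            raise ParameterError("n_causal_per_gene must be >= 1")

    def h2_bounds(self) -> tuple[float, float]:
        if isinstance(self.h2_cis, (tuple, list)):
            return float(self.h2_cis[0]), float(self.h2_cis[1])
        return float(self.h2_cis), float(self.h2_cis)

    def draw_h2(self, rng: np.random.Generator) -> float:
        lo, hi = self.h2_bounds()
        return lo if lo == hi else float(rng.uniform(lo, hi))


ARCHITECTURES = ("null", "single_gene", "gene_pair", "regionwide")


@dataclass
class EffectSpec:
    """Generative trait architecture.

    ``effect_size`` is the target fraction of trait (or liability)
    variance explained by the expression mediator.
    """

    architecture: str = "null"
    target_gene_ids: list[str] = field(default_factory=list)
    effect_size: float = 0.1
    trait_type: str = "quantitative"
    prevalence: float = 0.3
    trait_name: str = "trait"
    tissue_id: str | None = None
    covariate_r2: float = 0.02

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ParameterError(f"unknown architecture {self.architecture!r}")
        if not 0.0 <= self.effect_size < 1.0:
            raise ParameterError("effect_size must lie in [0, 1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ParameterError("prevalence must lie in (0, 1)")
        if self.architecture == "single_gene" and len(self.target_gene_ids) != 1:
            raise ParameterError("single_gene architecture needs exactly 1 target gene")
        if self.architecture == "gene_pair" and len(self.target_gene_ids) < 2:
            raise ParameterError("gene_pair architecture needs at least 2 target genes")
        if self.architecture == "regionwide" and not self.target_gene_ids:
            raise ParameterError("regionwide architecture needs target genes")
        if self.effect_size + self.covariate_r2 >= 1.0:
            raise ParameterError("effect_size + covariate_r2 must be < 1")


# --------------------------------------------------------------------------
# gene catalog
# --------------------------------------------------------------------------
def _lay_out_genes(
    rng: np.random.Generator,
    chrom: str,
    prefix: str,
    n_genes: int,
    slot_bp: float,
    start: int,
    *,
    total_bp: int | None = None,
) -> list[tuple[str, str, int, int]]:
    """Place ``n_genes`` consecutive genes, one per jittered slot.

    With ``total_bp`` the jittered slots are rescaled to span exactly that
    many bases, so every gene is guaranteed to fit inside
    [start, start + total_bp).
    """
    slots = slot_bp * rng.uniform(0.8, 1.25, size=n_genes)
    if total_bp is not None:
        slots = slots * (total_bp / slots.sum())
    rows = []
    pos = float(start)
    for i, slot in enumerate(slots):
        length = max(int(slot * rng.uniform(0.35, 0.6)), 200)
        offset = int(slot * rng.uniform(0.05, 0.3))
        g_start = int(pos) + offset
        rows.append((f"{prefix}{i + 1:03d}", chrom, g_start, g_start + length))
        pos += slot
    return rows


def generate_gene_catalog(
    n_background_genes: int,
    cnv_spec: CnvSpec,
    seed: int,
    *,
    n_background_chromosomes: int = 4,
    background_coding_fraction: float | None = None,
    flank_bp: int = 200_000,
) -> tuple[GeneCatalog, RegionDefinition]:
    """Build a synthetic catalog containing one CNV region.

    Background genes are laid out on ``n_background_chromosomes``
    chromosomes with the same per-gene spacing distribution as the CNV
    region, so that contiguous windows of the CNV's gene count have
    comparable physical spans (a prerequisite for control matching).
    """
    if n_background_genes <= 0:
        raise ParameterError("n_background_genes must be positive")
    rng = np.random.default_rng(seed)
    slot_bp = cnv_spec.length_bp / cnv_spec.n_genes

    region_start = 1_000_000
    region_end = region_start + cnv_spec.length_bp
    cnv_rows = _lay_out_genes(
        rng,
        "chrC",
        "CNV_G",
        cnv_spec.n_genes,
        slot_bp,
        region_start,
        total_bp=cnv_spec.length_bp,
    )

    n_coding = int(round(cnv_spec.n_genes * cnv_spec.coding_fraction))
    cnv_coding = np.zeros(cnv_spec.n_genes, dtype=bool)
    cnv_coding[rng.permutation(cnv_spec.n_genes)[:n_coding]] = True

    bg_fraction = (
        cnv_spec.coding_fraction
        if background_coding_fraction is None
        else background_coding_fraction
    )
    per_chrom = int(np.ceil(n_background_genes / n_background_chromosomes))
    bg_rows: list[tuple[str, str, int, int]] = []
    idx = 0
    for c in range(n_background_chromosomes):
        take = min(per_chrom, n_background_genes - idx)
        if take <= 0:
            break
        rows = _lay_out_genes(
            rng, f"chr{c + 1}", f"BG_C{c + 1}_G", take, slot_bp, 500_000
        )
        bg_rows.extend(rows)
        idx += take
    bg_coding = rng.random(len(bg_rows)) < bg_fraction

    records = []
    for (gid, chrom, s, e), coding in zip(cnv_rows, cnv_coding):
        bt = "protein_coding" if coding else str(rng.choice(NONCODING_BIOTYPES))
        records.append((gid, chrom, s, e, bt))
    for (gid, chrom, s, e), coding in zip(bg_rows, bg_coding):
        bt = "protein_coding" if coding else str(rng.choice(NONCODING_BIOTYPES))
        records.append((gid, chrom, s, e, bt))
    catalog = GeneCatalog(
        pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "biotype"])
    )
    region = RegionDefinition(
        region_id="CNV",
        chrom="chrC",
        start=region_start,
        end=region_end,
        member_gene_ids=[r[0] for r in cnv_rows],
        flank_bp=flank_bp,
    )
    region.validate_members(catalog)
    return catalog, region


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------
def simulate_genotype_panel(
    catalog: GeneCatalog,
    n_samples: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 5,
    ld_rho: float = 0.3,
    seed: int = 0,
    *,
    variants_per_gene: int = 20,
    cis_margin_bp: int = 5_000,
    sample_prefix: str = "S",
) -> GenotypePanel:
    """Simulate a dosage panel with block LD in each gene's cis window.

    Within a block of ``ld_block_size`` consecutive variants, haplotype
    alleles come from a compound-symmetric latent Gaussian (correlation
    ``ld_rho``) thresholded at the per-variant target MAF; the two
    haplotypes are independent and summed to a 0/1/2 dosage.
    """
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    if not 0.0 <= ld_rho < 1.0:
        raise ParameterError("ld_rho must lie in [0, 1)")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ParameterError("maf_range must lie within (0, 0.5]")
    if variants_per_gene < 1:
        raise ParameterError("variants_per_gene must be >= 1")
    rng = np.random.default_rng(seed)

    var_rows = []
    dosage_cols = []
    genes = catalog.genes
    for g in genes.itertuples(index=False):
        span_lo = max(g.start - cis_margin_bp, 1)
        span_hi = g.end + cis_margin_bp
        pos = np.sort(
            rng.choice(
                np.arange(span_lo, span_hi), size=variants_per_gene, replace=False
            )
        )
        mafs = rng.uniform(lo, hi, size=variants_per_gene)
        block_dosages = np.empty((n_samples, variants_per_gene), dtype=np.float32)
        for b0 in range(0, variants_per_gene, ld_block_size):
            b1 = min(b0 + ld_block_size, variants_per_gene)
            width = b1 - b0
            thresh = ndtri(mafs[b0:b1])
            dos = np.zeros((n_samples, width), dtype=np.int8)
            for _hap in range(2):
                shared = rng.standard_normal((n_samples, 1))
                eps = rng.standard_normal((n_samples, width))
                z = np.sqrt(ld_rho) * shared + np.sqrt(1.0 - ld_rho) * eps
                dos += (z < thresh).astype(np.int8)
            block_dosages[:, b0:b1] = dos
        dosage_cols.append(block_dosages)
        for k in range(variants_per_gene):
            var_rows.append(
                (
                    f"{g.gene_id}_v{k + 1}",
                    g.chrom,
                    int(pos[k]),
                    "A",
                    "G",
                    float(mafs[k]),
                )
            )

    variants = pd.DataFrame(
        var_rows,
        columns=["variant_id", "chrom", "pos", "ref_allele", "effect_allele", "maf"],
    )
    dosages = np.concatenate(dosage_cols, axis=1)
    order = variants.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    variants = variants.loc[order].reset_index(drop=True)
    dosages = dosages[:, order]
    sample_ids = [f"{sample_prefix}{i + 1:05d}" for i in range(n_samples)]
    return GenotypePanel(sample_ids=sample_ids, variants=variants, dosages=dosages)


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------
@dataclass
class EqtlTruth:
    """Ground-truth eQTL architecture retained for testing and mediation.

    ``weights`` maps (tissue_id, gene_id) to a (variant_ids, weight
    vector) pair on the standardized-dosage scale, scaled so that the
    genetic value of gene g in a large panel has variance ~h2_cis(g).
    """

    weights: dict[tuple[str, str], tuple[list[str], np.ndarray]]
    h2_by_gene: dict[str, float]
    causal_by_gene: dict[str, list[str]]

    def genetic_value(
        self, panel: GenotypePanel, gene_id: str, tissue_id: str
    ) -> np.ndarray:
        """True genetic expression value of a gene in an arbitrary panel."""
        variant_ids, w = self.weights[(tissue_id, gene_id)]
        d = panel.dosage_frame(variant_ids).to_numpy()
        sd = d.std(axis=0)
        sd[sd == 0] = 1.0
        d_std = (d - d.mean(axis=0)) / sd
        return d_std @ w

    def total_expression(
        self,
        panel: GenotypePanel,
        gene_id: str,
        tissue_id: str,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Genetic value plus fresh environmental noise at the gene's h2."""
        g = self.genetic_value(panel, gene_id, tissue_id)
        h2 = self.h2_by_gene[gene_id]
        return g + np.sqrt(max(1.0 - h2, 0.0)) * rng.standard_normal(panel.n_samples)


@dataclass
class ExpressionPanel:
    """Observed multi-tissue expression over a training panel's samples.

    ``expression`` holds the inverse-normal-transformed vectors actually
    used for model training; ``raw_expression`` the pre-transform values;
    ``genetic_values`` the noise-free genetic component. All three are
    keyed by (tissue_id, gene_id); per-gene tissue availability may vary.
    """

    tissue_ids: list[str]
    sample_ids: list[str]
    expression: dict[tuple[str, str], np.ndarray]
    raw_expression: dict[tuple[str, str], np.ndarray]
    genetic_values: dict[tuple[str, str], np.ndarray]
    truth: EqtlTruth

    def gene_ids(self) -> list[str]:
        return sorted({g for (_, g) in self.expression})

    def tissues_for(self, gene_id: str) -> list[str]:
        return [t for (t, g) in self.expression if g == gene_id]


def simulate_expression_panel(
    panel: GenotypePanel,
    catalog: GeneCatalog,
    eqtl_spec: EqtlSpec,
    n_tissues: int,
    seed: int,
    *,
    cis_window_bp: int = 10_000,
) -> ExpressionPanel:
    """Simulate INT-ed expression with a sparse cis architecture.

    Per gene, ``n_causal_per_gene`` cis variants receive effect weights,
    drawn from the gene's proximal window (``cis_window_bp``, default
    10 kb, i.e. the gene's own regulatory neighbourhood — a broad window
    would assign causal variants belonging to neighbouring genes and
    blur the single-gene architecture; model training may still search
    a much wider cis window);
    tissue t's weights are sqrt(s) * shared + sqrt(1-s) * specific with
    s = ``cross_tissue_sharing``, so the between-tissue correlation of a
    gene's expression is approximately h2_cis * s.
    """
    if n_tissues < 1:
        raise ParameterError("n_tissues must be >= 1")
    rng = np.random.default_rng(seed)
    tissue_ids = [f"T{t + 1}" for t in range(n_tissues)]
    expression: dict[tuple[str, str], np.ndarray] = {}
    raw: dict[tuple[str, str], np.ndarray] = {}
    genetic: dict[tuple[str, str], np.ndarray] = {}
    weights: dict[tuple[str, str], tuple[list[str], np.ndarray]] = {}
    h2_by_gene: dict[str, float] = {}
    causal_by_gene: dict[str, list[str]] = {}

    for g in catalog.genes.itertuples(index=False):
        cis = panel.cis_variant_ids(g.chrom, g.start, g.end, cis_window_bp)
        if not cis:
            continue
        # causal variants are the gene's own simulated regulatory
        # variants; neighbouring genes' variants falling in the window
        # are decoys, not candidate causals
        own = [v for v in cis if v.startswith(f"{g.gene_id}_v")]
        candidates = own or cis
        k = min(eqtl_spec.n_causal_per_gene, len(candidates))
        causal = [candidates[i] for i in rng.choice(len(candidates), size=k, replace=False)]
        h2 = eqtl_spec.draw_h2(rng)
        h2_by_gene[g.gene_id] = h2
        causal_by_gene[g.gene_id] = causal
        d = panel.dosage_frame(causal).to_numpy()
        sd = d.std(axis=0)
        sd[sd == 0] = 1.0
        d_std = (d - d.mean(axis=0)) / sd

        s = eqtl_spec.cross_tissue_sharing
        w_shared = rng.standard_normal(k)
        for t in tissue_ids:
            w_t = np.sqrt(s) * w_shared + np.sqrt(1.0 - s) * rng.standard_normal(k)
            raw_g = d_std @ w_t
            sd_g = raw_g.std()
            if sd_g == 0:
                continue
            g_scaled = np.sqrt(h2) * (raw_g - raw_g.mean()) / sd_g
            noise = np.sqrt(max(1.0 - h2, 0.0)) * rng.standard_normal(panel.n_samples)
            pre = g_scaled + noise
            genetic[(t, g.gene_id)] = g_scaled
            raw[(t, g.gene_id)] = pre
            expression[(t, g.gene_id)] = (
                pre.copy() if np.ptp(pre) == 0 else inverse_normal_transform(pre)
            )
            weights[(t, g.gene_id)] = (causal, np.sqrt(h2) * w_t / sd_g)

    truth = EqtlTruth(
        weights=weights, h2_by_gene=h2_by_gene, causal_by_gene=causal_by_gene
    )
    return ExpressionPanel(
        tissue_ids=tissue_ids,
        sample_ids=list(panel.sample_ids),
        expression=expression,
        raw_expression=raw,
        genetic_values=genetic,
        truth=truth,
    )


# --------------------------------------------------------------------------
# traits
# --------------------------------------------------------------------------
@dataclass
class CovariateSpec:
    """Synthetic covariates: age, age^2 and a few genotype-free PCs."""

    n_pcs: int = 5
    include_age: bool = True


def simulate_covariates(
    n_samples: int, rng: np.random.Generator, spec: CovariateSpec | None = None
) -> pd.DataFrame:
    spec = spec or CovariateSpec()
    cols = {}
    if spec.include_age:
        age = rng.normal(55.0, 8.0, size=n_samples)
        cols["age"] = age
        cols["age2"] = age**2
    for i in range(spec.n_pcs):
        cols[f"pc{i + 1}"] = rng.standard_normal(n_samples)
    return pd.DataFrame(cols)


def trait_mediator(
    panel: GenotypePanel,
    truth: EqtlTruth,
    effect_spec: EffectSpec,
    rng: np.random.Generator,
    tissue_id: str,
) -> np.ndarray | None:
    """The standardized expression mediator for the requested architecture.

    "True expression" of a gene in the cohort means its genetic value
    plus fresh environmental noise at the gene's cis heritability, so the
    mediator is only partly recoverable from genotypes — as in real
    expression-mediated traits.
    """
    arch = effect_spec.architecture
    if arch == "null":
        return None
    if arch == "regionwide" and effect_spec.tissue_id is None:
        # the region-wide architecture is a tissue-agnostic deviation of
        # the whole segment: average each gene's expression over tissues
        exprs = []
        for g in effect_spec.target_gene_ids:
            tissues = sorted({t for (t, gg) in truth.weights if gg == g})
            per_tissue = [
                truth.total_expression(panel, g, t, rng) for t in tissues
            ]
            exprs.append(np.mean(per_tissue, axis=0))
        return standardize(np.sum(exprs, axis=0))
    exprs = [
        truth.total_expression(panel, g, tissue_id, rng)
        for g in effect_spec.target_gene_ids
    ]
    if arch == "single_gene":
        m = exprs[0]
    elif arch == "gene_pair":
        m = inverse_normal_transform(exprs[0] + exprs[1])
    else:  # regionwide with a pinned tissue
        m = np.sum(exprs, axis=0)
    return standardize(m)


def simulate_trait(
    panel: GenotypePanel,
    truth: EqtlTruth,
    effect_spec: EffectSpec,
    seed: int,
    *,
    covariate_spec: CovariateSpec | None = None,
) -> PhenotypeTable:
    """Simulate a trait mediated through expression.

    Quantitative traits: y = sqrt(es)*mediator + sqrt(c)*covariate score
    + sqrt(1 - es - c)*noise, all components standardized, so the
    realized variance explained by the mediator matches ``effect_size``
    up to Monte-Carlo error. Binary traits threshold the same liability
    at the (1 - prevalence) normal quantile.
    """
    rng = np.random.default_rng(seed)
    n = panel.n_samples
    covariates = simulate_covariates(n, rng, covariate_spec)
    cov_score = np.zeros(n)
    if len(covariates.columns) and effect_spec.covariate_r2 > 0:
        coefs = rng.standard_normal(len(covariates.columns))
        raw = covariates.to_numpy(dtype=float)
        raw = (raw - raw.mean(axis=0)) / np.where(raw.std(axis=0) == 0, 1, raw.std(axis=0))
        cov_score = standardize(raw @ coefs)

    tissue = effect_spec.tissue_id or "T1"
    mediator = trait_mediator(panel, truth, effect_spec, rng, tissue)
    es = effect_spec.effect_size if mediator is not None else 0.0
    c = effect_spec.covariate_r2 if cov_score.any() else 0.0
    liability = np.sqrt(max(1.0 - es - c, 0.0)) * rng.standard_normal(n)
    if mediator is not None:
        liability = liability + np.sqrt(es) * mediator
    if c > 0:
        liability = liability + np.sqrt(c) * cov_score

    if effect_spec.trait_type == "binary":
        values = (liability > ndtri(1.0 - effect_spec.prevalence)).astype(float)
    else:
        values = liability
    return PhenotypeTable(
        sample_ids=list(panel.sample_ids),
        trait_name=effect_spec.trait_name,
        trait_type=effect_spec.trait_type,
        values=values,
        covariates=covariates,
    )


# --------------------------------------------------------------------------
# GWAS summary statistics
# --------------------------------------------------------------------------
def compute_gwas_summary(
    panel: GenotypePanel, phenotypes: PhenotypeTable
) -> SummaryStats:
    """Per-variant linear association of trait on dosage with covariates.

    Binary traits are regressed on the 0/1 coding with the same linear
    model, keeping effect sizes on the variance-explained scale used for
    the downstream model comparisons.
    """
    if list(panel.sample_ids) != list(phenotypes.sample_ids):
        raise AlignmentError("panel and phenotype sample ids differ")
    y = phenotypes.values
    beta, se, p = bulk_linear_association(
        y, panel.dosages.astype(float), phenotypes.covariate_matrix()
    )
    table = pd.DataFrame(
        {
            "variant_id": panel.variants["variant_id"],
            "effect_allele": panel.variants["effect_allele"],
            "other_allele": panel.variants["ref_allele"],
            "beta": beta,
            "se": np.where(np.isfinite(se) & (se > 0), se, np.nan),
            "p": p,
            "n": phenotypes.n,
        }
    )
    # constant-dosage variants carry no information; drop them
    table = table.dropna(subset=["se"]).reset_index(drop=True)
    return SummaryStats(table)
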