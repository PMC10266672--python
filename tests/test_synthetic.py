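"""Generative-model checks: genotypes, expression, traits, GWAS."""

import numpy as np
import pytest
from scipy import stats

import cnvpairtwas as ct
from cnvpairtwas._stats import bulk_linear_association, linear_association
from cnvpairtwas.exceptions import AlignmentError, ParameterError


# ---------------------------------------------------------------- genotypes
def test_dosage_mean_matches_binomial_expectation():
    catalog, region = ct.generate_gene_catalog(2, ct.CnvSpec(n_genes=3), seed=1)
    panel = ct.simulate_genotype_panel(
        catalog, 1000, maf_range=(0.5, 0.5), ld_rho=0.0, seed=2, variants_per_gene=8
    )
    means = panel.dosages.mean(axis=0)
    band = 3 * np.sqrt(0.5 / 1000) * 2
    assert (np.abs(means - 1.0) < band).all()
    assert set(np.unique(panel.dosages)) <= {0.0, 1.0, 2.0}


def test_zero_ld_gives_uncorrelated_dosages():
    catalog, _ = ct.generate_gene_catalog(2, ct.CnvSpec(n_genes=3), seed=1)
    panel = ct.simulate_genotype_panel(
        catalog, 1000, ld_rho=0.0, seed=3, variants_per_gene=10
    )
    corr = np.corrcoef(panel.dosages, rowvar=False)
    off = np.abs(corr[np.triu_indices_from(corr, k=1)])
    assert off.mean() < 0.05


def test_ld_blocks_raise_within_block_correlation():
    catalog, _ = ct.generate_gene_catalog(2, ct.CnvSpec(n_genes=3), seed=1)
    panel = ct.simulate_genotype_panel(
        catalog, 2000, ld_rho=0.8, ld_block_size=5, seed=3, variants_per_gene=10
    )
    # variants of one gene, first block of 5 (positions are sorted per gene)
    gene = catalog.genes["gene_id"].iloc[0]
    cols = [i for i, v in enumerate(panel.variants["variant_id"]) if v.startswith(gene)][:5]
    corr = np.corrcoef(panel.dosages[:, cols], rowvar=False)
    off = corr[np.triu_indices_from(corr, k=1)]
    assert off.mean() > 0.3


def test_genotype_determinism_and_parameter_errors(universe):
    catalog = universe["catalog"]
    a = ct.simulate_genotype_panel(catalog, 50, seed=42, variants_per_gene=4)
    b = ct.simulate_genotype_panel(catalog, 50, seed=42, variants_per_gene=4)
    np.testing.assert_array_equal(a.dosages, b.dosages)
    with pytest.raises(ParameterError):
        ct.simulate_genotype_panel(catalog, 50, ld_rho=1.0, seed=1)
    with pytest.raises(ParameterError):
        ct.simulate_genotype_panel(catalog, 50, maf_range=(0.0, 0.5), seed=1)


# --------------------------------------------------------------- expression
def test_expression_invariants_and_h2_extremes():
    catalog, region = ct.generate_gene_catalog(2, ct.CnvSpec(n_genes=3), seed=1)
    sub = catalog.subset(region.member_gene_ids)
    panel = ct.simulate_genotype_panel(catalog, 500, seed=4, variants_per_gene=8)

    null_expr = ct.simulate_expression_panel(
        panel, sub, ct.EqtlSpec(h2_cis=0.0), 1, seed=5
    )
    for key, vec in null_expr.expression.items():
        assert abs(vec.mean()) < 1e-8
        g = null_expr.genetic_values[key]
        if g.std() > 0:
            assert abs(np.corrcoef(g, vec)[0, 1]) < 0.1

    perfect = ct.simulate_expression_panel(
        panel, sub, ct.EqtlSpec(n_causal_per_gene=1, h2_cis=1.0), 1, seed=6
    )
    for (t, gene), pre in perfect.raw_expression.items():
        (vid,), w = perfect.truth.weights[(t, gene)]
        d = panel.dosage_frame([vid]).to_numpy()[:, 0]
        d_std = (d - d.mean()) / d.std()
        np.testing.assert_allclose(pre, np.sign(w[0]) * d_std, atol=1e-10)

    with pytest.raises(ParameterError):
        ct.EqtlSpec(h2_cis=1.5)


def test_cross_tissue_sharing_yields_target_correlation():
    catalog, region = ct.generate_gene_catalog(2, ct.CnvSpec(n_genes=4), seed=1)
    sub = catalog.subset(region.member_gene_ids)
    panel = ct.simulate_genotype_panel(catalog, 500, seed=7, variants_per_gene=8)
    # between-tissue correlation ~ h2 * sharing; tune for a 0.8 target
    expr = ct.simulate_expression_panel(
        panel,
        sub,
        ct.EqtlSpec(h2_cis=0.9, cross_tissue_sharing=0.8 / 0.9),
        2,
        seed=8,
    )
    corrs = []
    for g in region.member_gene_ids:
        a = expr.raw_expression[("T1", g)]
        b = expr.raw_expression[("T2", g)]
        corrs.append(np.corrcoef(a, b)[0, 1])
    assert abs(np.mean(corrs) - 0.8) < 0.1


# -------------------------------------------------------------------- traits
def test_quantitative_effect_size_is_realized():
    catalog, region = ct.generate_gene_catalog(2, ct.CnvSpec(n_genes=3), seed=1)
    sub = catalog.subset(region.member_gene_ids)
    panel = ct.simulate_genotype_panel(catalog, 5000, seed=9, variants_per_gene=8)
    # h2=1 makes the mediator equal the gene's genetic value, which the
    # truth object can recompute exactly
    expr = ct.simulate_expression_panel(panel, sub, ct.EqtlSpec(h2_cis=1.0), 1, seed=10)
    gene = region.member_gene_ids[0]
    spec = ct.EffectSpec(
        architecture="single_gene", target_gene_ids=[gene], effect_size=0.10
    )
    pheno = ct.simulate_trait(panel, expr.truth, spec, seed=11)
    mediator = expr.truth.genetic_value(panel, gene, "T1")
    r = np.corrcoef(mediator, pheno.values)[0, 1]
    assert 0.07 <= r**2 <= 0.13


def test_binary_prevalence_and_errors(universe):
    panel, expr = universe["panel"], universe["expr"]
    ns = 1000
    big = ct.simulate_genotype_panel(universe["catalog"], ns, seed=12, variants_per_gene=4)
    expr_big = ct.simulate_expression_panel(
        big, universe["catalog"].subset(universe["region"].member_gene_ids),
        ct.EqtlSpec(), 1, seed=13,
    )
    spec = ct.EffectSpec(
        architecture="null", trait_type="binary", prevalence=0.30
    )
    pheno = ct.simulate_trait(big, expr_big.truth, spec, seed=14)
    assert abs(pheno.values.mean() - 0.30) <= 0.045
    with pytest.raises(ParameterError):
        ct.EffectSpec(architecture="gene_pair", target_gene_ids=["only_one"])
    with pytest.raises(ParameterError):
        ct.EffectSpec(architecture="null", effect_size=1.0)


# ---------------------------------------------------------------------- GWAS
def test_causal_variant_attains_minimum_p():
    catalog, region = ct.generate_gene_catalog(2, ct.CnvSpec(n_genes=3), seed=1)
    sub = catalog.subset(region.member_gene_ids)
    panel = ct.simulate_genotype_panel(catalog, 2000, seed=15, variants_per_gene=8)
    expr = ct.simulate_expression_panel(
        panel, sub, ct.EqtlSpec(n_causal_per_gene=1, h2_cis=1.0), 1, seed=16
    )
    gene = region.member_gene_ids[0]
    spec = ct.EffectSpec(
        architecture="single_gene", target_gene_ids=[gene], effect_size=0.25
    )
    pheno = ct.simulate_trait(panel, expr.truth, spec, seed=17)
    ss = ct.compute_gwas_summary(panel, pheno).table
    causal = expr.truth.causal_by_gene[gene][0]
    assert ss.loc[ss["p"].idxmin(), "variant_id"] == causal


def test_null_gwas_p_are_calibrated(universe):
    panel = universe["panel"]
    spec = ct.EffectSpec(architecture="null")
    pheno = ct.simulate_trait(panel, universe["expr"].truth, spec, seed=18)
    ss = ct.compute_gwas_summary(panel, pheno).table
    frac = (ss["p"] < 0.05).mean()
    assert abs(frac - 0.05) <= 0.02
    with pytest.raises(AlignmentError):
        bad = ct.PhenotypeTable(
            sample_ids=["x1", "x2"], trait_name="t", trait_type="quantitative",
            values=np.zeros(2),
        )
        ct.compute_gwas_summary(panel, bad)


def test_ols_helpers_match_statsmodels(rng):
    import statsmodels.api as sm

    n = 40
    cov = rng.standard_normal((n, 2))
    x = rng.standard_normal(n)
    y = 0.4 * x + cov @ [0.2, -0.1] + rng.standard_normal(n)
    res = linear_association(y, x, cov)
    design = sm.add_constant(np.column_stack([x, cov]))
    fit = sm.OLS(y, design).fit()
    np.testing.assert_allclose(res.beta, fit.params[1], rtol=1e-10)
    np.testing.assert_allclose(res.se, fit.bse[1], rtol=1e-10)
    np.testing.assert_allclose(res.p, fit.pvalues[1], rtol=1e-8)

    xs = rng.standard_normal((n, 5))
    betas, ses, ps = bulk_linear_association(y, xs, cov)
    for j in range(5):
        single = linear_association(y, xs[:, j], cov)
        np.testing.assert_allclose(betas[j], single.beta, rtol=1e-10)
        np.testing.assert_allclose(ses[j], single.se, rtol=1e-10)
        np.testing.assert_allclose(ps[j], single.p, rtol=1e-8)


def test_gwas_betas_track_eqtl_weights_under_mediation():
    """single-gene architecture: marginal GWAS effects are proportional
    to the causal eQTL weights (no-LD design)."""
    catalog, region = ct.generate_gene_catalog(2, ct.CnvSpec(n_genes=3), seed=1)
    sub = catalog.subset(region.member_gene_ids)
    panel = ct.simulate_genotype_panel(
        catalog, 5000, ld_rho=0.0, seed=19, variants_per_gene=10
    )
    expr = ct.simulate_expression_panel(panel, sub, ct.EqtlSpec(h2_cis=0.5), 1, seed=20)
    gene = region.member_gene_ids[0]
    spec = ct.EffectSpec(
        architecture="single_gene", target_gene_ids=[gene], effect_size=0.2
    )
    pheno = ct.simulate_trait(panel, expr.truth, spec, seed=21)
    ss = ct.compute_gwas_summary(panel, pheno).indexed()

    vids, w = expr.truth.weights[("T1", gene)]
    sds = panel.dosage_frame(vids).to_numpy().std(axis=0)
    observed = ss.loc[vids, "beta"].to_numpy() * sds  # per-SD scale
    assert np.corrcoef(observed, w)[0, 1] > 0.9
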