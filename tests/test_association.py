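"""Association-stage oracles: prediction, per-tissue OLS, summary-based
z, cross-tissue combination, meta-analysis, permutation thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import ndtri

import cnvpairtwas as ct
from cnvpairtwas._stats import bulk_linear_association
from cnvpairtwas.association import prediction_frame
from cnvpairtwas.exceptions import NumericalInputError, ParameterError
from cnvpairtwas.expression_models import WeightModel


def _single_snp_model(panel, vid, weight, swap_alleles=False):
    row = panel.variants.set_index("variant_id").loc[vid]
    d = panel.dosage_frame([vid]).to_numpy()[:, 0]
    eff, ref = row["effect_allele"], row["ref_allele"]
    if swap_alleles:
        eff, ref = ref, eff
    return WeightModel(
        "unit", "T1",
        pd.DataFrame(
            [(vid, eff, ref, weight, float(d.mean()), float(d.std()))],
            columns=["variant_id", "effect_allele", "ref_allele", "weight", "train_mean", "train_sd"],
        ),
        0.5, 0.001,
    )


def _flipped_panel(panel, vid):
    """Same genotypes with ref/effect labels exchanged and d -> 2-d."""
    variants = panel.variants.copy()
    i = variants.index[variants["variant_id"] == vid][0]
    variants.loc[i, ["ref_allele", "effect_allele"]] = (
        variants.loc[i, "effect_allele"],
        variants.loc[i, "ref_allele"],
    )
    dosages = panel.dosages.copy()
    dosages[:, i] = 2.0 - dosages[:, i]
    return ct.GenotypePanel(panel.sample_ids, variants, dosages)


def test_single_snp_prediction_is_weighted_standardized_dosage(universe):
    panel = universe["panel"]
    vid = panel.variants["variant_id"].iloc[5]
    model = _single_snp_model(panel, vid, weight=0.7)
    pred = ct.predict_expression(model, panel)
    d = panel.dosage_frame([vid]).to_numpy()[:, 0]
    np.testing.assert_allclose(pred.values, 0.7 * (d - d.mean()) / d.std())
    assert pred.coverage == 1.0

    empty = WeightModel("u", "T1", pd.DataFrame(), 0.0, 1.0)
    assert ct.predict_expression(empty, panel).missing


def test_prediction_invariant_to_allele_encoding(universe):
    panel = universe["panel"]
    vid = panel.variants["variant_id"].iloc[5]
    model = _single_snp_model(panel, vid, weight=-1.3)
    flipped = _flipped_panel(panel, vid)
    np.testing.assert_allclose(
        ct.predict_expression(model, panel).values,
        ct.predict_expression(model, flipped).values,
        atol=1e-6,
    )


def test_associate_tissue_matches_closed_form_ols(universe, rng):
    import statsmodels.api as sm

    panel = universe["panel"]
    x = rng.standard_normal(panel.n_samples)
    y = 0.3 * x + rng.standard_normal(panel.n_samples)
    pheno = ct.PhenotypeTable(panel.sample_ids, "t", "quantitative", y)
    rec = ct.associate_tissue(x, pheno, unit_id="u")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    np.testing.assert_allclose(rec.effect, fit.params[1], rtol=1e-10)
    np.testing.assert_allclose(rec.se, fit.bse[1], rtol=1e-10)
    assert rec.direction == 1

    perfect = ct.associate_tissue(y, pheno, unit_id="u")
    assert perfect.p <= 1e-300 and perfect.direction == 1

    constant = ct.associate_tissue(np.ones(panel.n_samples), pheno, unit_id="u")
    assert constant is None


def test_null_association_p_values_are_uniform(rng):
    n = 120
    x = rng.standard_normal(n)
    ps = []
    for _ in range(400):
        y = rng.standard_normal(n)
        _, _, p = bulk_linear_association(y, x[:, None])
        ps.append(p[0])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_spredixcan_single_snp_reduces_to_signed_z(universe):
    panel = universe["panel"]
    expr = universe["expr"]
    spec = ct.EffectSpec(
        architecture="single_gene",
        target_gene_ids=[universe["region"].member_gene_ids[0]],
        effect_size=0.1,
    )
    pheno = ct.simulate_trait(panel, expr.truth, spec, seed=23)
    ss = ct.compute_gwas_summary(panel, pheno)
    vid = expr.truth.causal_by_gene[spec.target_gene_ids[0]][0]
    row = ss.indexed().loc[vid]
    z_snp = row["beta"] / row["se"]
    for w in (0.8, -0.8):
        model = _single_snp_model(panel, vid, weight=w)
        rec = ct.spredixcan_z(model, ss, panel)
        np.testing.assert_allclose(rec.effect, np.sign(w) * z_snp, rtol=1e-10)

    # harmonization: swapping alleles in the summary stats and negating
    # beta leaves the unit z unchanged
    flipped_table = ss.table.copy()
    i = flipped_table.index[flipped_table["variant_id"] == vid][0]
    flipped_table.loc[i, ["effect_allele", "other_allele"]] = (
        flipped_table.loc[i, "other_allele"],
        flipped_table.loc[i, "effect_allele"],
    )
    flipped_table.loc[i, "beta"] *= -1
    model = _single_snp_model(panel, vid, weight=0.8)
    rec_orig = ct.spredixcan_z(model, ss, panel)
    rec_flip = ct.spredixcan_z(model, ct.SummaryStats(flipped_table), panel)
    np.testing.assert_allclose(rec_orig.effect, rec_flip.effect, rtol=1e-10)


def test_cross_tissue_individual_reductions(universe, rng):
    panel = universe["panel"]
    n = panel.n_samples
    x = rng.standard_normal(n)
    y = 0.2 * x + rng.standard_normal(n)
    pheno = ct.PhenotypeTable(panel.sample_ids, "t", "quantitative", y)
    single = ct.associate_tissue(x, pheno, unit_id="u")
    one = ct.combine_tissues_individual({"T1": x}, pheno, unit_id="u")
    np.testing.assert_allclose(one.p, single.p, rtol=1e-8)
    # F with one numerator df equals t^2
    np.testing.assert_allclose(one.effect, (single.effect / single.se) ** 2, rtol=1e-8)

    dup = ct.combine_tissues_individual({"T1": x, "T2": x.copy()}, pheno, unit_id="u")
    np.testing.assert_allclose(dup.p, single.p, rtol=1e-8)


def test_cross_tissue_summary_eigen_oracle():
    z = {"T1": 1.4, "T2": -0.5, "T3": 2.2}
    tissues = sorted(z)
    ident = pd.DataFrame(np.eye(3), index=tissues, columns=tissues)
    rec = ct.combine_tissues_summary(z, ident, unit_id="u")
    zv = np.array([z[t] for t in tissues])
    np.testing.assert_allclose(rec.effect, (zv**2).sum(), rtol=1e-10)
    np.testing.assert_allclose(rec.n_effective, 3)
    np.testing.assert_allclose(rec.p, stats.chi2.sf((zv**2).sum(), 3), rtol=1e-10)

    ones = pd.DataFrame(np.ones((3, 3)), index=tissues, columns=tissues)
    rec1 = ct.combine_tissues_summary(z, ones, unit_id="u")
    np.testing.assert_allclose(rec1.effect, zv.mean() ** 2, rtol=1e-10)
    assert rec1.n_effective == 1

    bad = pd.DataFrame(
        [[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
        index=tissues, columns=tissues,
    )
    with pytest.raises(NumericalInputError):
        ct.combine_tissues_summary(z, bad, unit_id="u")


def _rec(p, direction, unit="u"):
    return ct.AssociationRecord(
        unit_id=unit, trait="t", level="cross_tissue", effect=0.0,
        p=p, direction=direction,
    )


def test_meta_analysis_weighted_z_arithmetic():
    single = ct.meta_analyze([_rec(0.01, 1)], [1000])
    np.testing.assert_allclose(single.effect, ndtri(1 - 0.01 / 2), rtol=1e-10)

    two = ct.meta_analyze([_rec(0.01, 1), _rec(0.01, 1)], [1000, 1000])
    np.testing.assert_allclose(
        two.effect, np.sqrt(2) * ndtri(1 - 0.01 / 2), rtol=1e-10
    )

    opp = ct.meta_analyze([_rec(0.01, 1), _rec(0.01, -1)], [1000, 1000])
    assert opp.effect == 0.0 and opp.p == 1.0 and opp.direction == 0

    clamped = ct.meta_analyze([_rec(1e-320, 1)], [100])  # clamps, no inf
    assert np.isfinite(clamped.effect)


def test_meta_z_is_linear_in_cohort_z():
    # adding a cohort changes z_meta by exactly its weighted contribution
    z1, z2 = 1.7, -0.6
    p1, p2 = 2 * stats.norm.sf(abs(z1)), 2 * stats.norm.sf(abs(z2))
    n1, n2 = 4000, 1000
    base = ct.meta_analyze([_rec(p1, 1)], [n1])
    both = ct.meta_analyze([_rec(p1, 1), _rec(p2, -1)], [n1, n2])
    w1, w2 = np.sqrt(n1), np.sqrt(n2)
    np.testing.assert_allclose(
        both.effect, (w1 * z1 + w2 * z2) / np.sqrt(w1**2 + w2**2), rtol=1e-8
    )
    assert abs(both.effect - base.effect * w1 / np.sqrt(w1**2 + w2**2)) <= abs(
        w2 * z2 / np.sqrt(w1**2 + w2**2)
    ) + 1e-12


def test_permutation_threshold_oracles(rng):
    assert ct.permutation_threshold([[0.01], [0.02], [0.04]]) == pytest.approx(0.02)
    pvals = rng.uniform(size=100)
    assert ct.permutation_threshold([pvals]) == pytest.approx(
        np.percentile(pvals, 5.0)
    )
    # 30 regions x 100 iid uniforms: threshold concentrates near 0.05
    draws = [rng.uniform(size=100) for _ in range(30)]
    assert abs(ct.permutation_threshold(draws) - 0.05) <= 0.02
    with pytest.raises(ParameterError):
        ct.permutation_threshold([])


def test_prediction_frame_collects_units(trained_models, universe):
    frame = prediction_frame(
        [m for m in trained_models if not m.is_empty],
        universe["panel"],
        tissue_id="T1",
        pairs=False,
    )
    assert frame.shape[0] == universe["panel"].n_samples
    assert all("|" not in c for c in frame.columns)
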