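"""Adjusted-R2 model comparison and the CNV-vs-control chi-square."""

import numpy as np
import pytest

import cnvpairtwas as ct
from cnvpairtwas.exceptions import ParameterError
from cnvpairtwas.variance_comparison import TallyRow, _winner, adjusted_r2


def test_adjusted_r2_perfect_fit_and_na_marker(rng):
    x = rng.standard_normal((30, 2))
    y = x @ [1.0, -2.0] + 3.0
    assert adjusted_r2(y, x) == pytest.approx(1.0)
    assert np.isnan(adjusted_r2(y[:3], x[:3]))  # n <= k + 1


def test_adjusted_r2_matches_hand_computed_formula():
    # 4-point worked example
    y = np.array([1.0, 2.0, 2.5, 4.0])
    x = np.array([[1.0], [2.0], [3.0], [4.0]])
    n, k = 4, 1
    beta = np.polyfit(x[:, 0], y, 1)
    resid = y - np.polyval(beta, x[:, 0])
    r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
    expected = 1 - (1 - r2) * (n - 1) / (n - k - 1)
    assert adjusted_r2(y, x) == pytest.approx(expected, rel=1e-12)

    import statsmodels.api as sm

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    assert adjusted_r2(y, x) == pytest.approx(fit.rsquared_adj, rel=1e-12)


def test_adjusted_r2_unbiased_under_null(rng):
    vals = []
    for _ in range(200):
        x = rng.standard_normal((1000, 10))
        y = rng.standard_normal(1000)
        vals.append(adjusted_r2(y, x))
    assert abs(np.mean(vals)) < 0.01


def test_winner_tie_break_priority():
    assert _winner({"single": 0.1, "interaction": 0.1, "pairwise": 0.1}) == "single"
    assert _winner({"single": 0.0, "interaction": 0.2, "pairwise": 0.2}) == "interaction"
    assert _winner({"single": 0.0, "interaction": 0.1, "pairwise": 0.2}) == "pairwise"


def _toy_rows(n_pairwise, n_total, region):
    rows = []
    for i in range(n_total):
        winner = "pairwise" if i < n_pairwise else "single"
        rows.append(
            TallyRow("C1", f"T{i}", region, 0.01, 0.01, 0.02 if winner == "pairwise" else 0.0, winner)
        )
    return rows


def test_compare_regions_chi_square_oracle():
    # identical proportions -> statistic 0, p 1
    stat, p = ct.compare_regions(_toy_rows(50, 100, "CNV"), _toy_rows(500, 1000, "CTRL"))
    assert stat == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0)

    # textbook Pearson chi-square from expected counts
    table = np.array([[40.0, 9.0], [300.0, 700.0]])
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    oracle = ((table - expected) ** 2 / expected).sum()
    stat, p = ct.compare_regions(_toy_rows(40, 49, "CNV"), _toy_rows(300, 1000, "CTRL"))
    assert stat == pytest.approx(oracle, rel=1e-10)
    from scipy.stats import chi2

    assert p == pytest.approx(chi2.sf(oracle, 1), rel=1e-10)

    # doubling every cell doubles the statistic
    stat2, p2 = ct.compare_regions(_toy_rows(80, 98, "CNV"), _toy_rows(600, 2000, "CTRL"))
    assert stat2 == pytest.approx(2 * stat, rel=1e-10)
    assert p2 < p

    with pytest.raises(ParameterError):
        ct.compare_regions(_toy_rows(0, 10, "CNV"), _toy_rows(0, 100, "CTRL"))


def _tally_setup(universe, trained_models, arch, targets, seed, n_cohort=2500):
    from cnvpairtwas.association import prediction_frame

    catalog, region, expr = universe["catalog"], universe["region"], universe["expr"]
    cohort = ct.simulate_genotype_panel(catalog, n_cohort, seed=900 + seed, variants_per_gene=10)
    models = ct.filter_models(trained_models)
    singles, pairs = {}, {}
    for t in ("T1", "T2"):
        singles[("C1", t)] = prediction_frame(models, cohort, tissue_id=t, pairs=False)
        pairs[("C1", t)] = prediction_frame(models, cohort, tissue_id=t, pairs=True)
    spec = ct.EffectSpec(architecture=arch, target_gene_ids=targets, effect_size=0.08)
    pheno = ct.simulate_trait(cohort, expr.truth, spec, seed=700 + seed)
    return ct.tally_best_models(singles, pairs, {"C1": pheno}, region.region_id)


def test_tally_recovers_pairwise_architecture(universe, trained_models):
    region = universe["region"]
    pair_targets = region.member_gene_ids[:2]
    pair_wins = rows_total = 0
    for seed in range(8):
        rows = _tally_setup(universe, trained_models, "gene_pair", pair_targets, seed)
        pair_wins += sum(r.winner == "pairwise" for r in rows)
        rows_total += len(rows)
        # conservation: winners tally over every evaluated row
        assert len(rows) == len([r.winner for r in rows])
    assert pair_wins > rows_total / 2  # pair trait: pairwise design dominates


def test_tally_prefers_single_design_for_single_gene_trait():
    """With accurate single-gene models and many pairs, the adjusted-R2
    penalty (which grows with the pairwise design's k) should hand
    single-gene traits to the parsimonious single design."""
    from cnvpairtwas.association import prediction_frame
    from cnvpairtwas.expression_models import train_region_models

    catalog, region = ct.generate_gene_catalog(
        10, ct.CnvSpec(n_genes=10, length_bp=800_000), seed=301
    )
    train = ct.simulate_genotype_panel(catalog, 500, seed=302, variants_per_gene=10)
    expr = ct.simulate_expression_panel(
        train, catalog.subset(region.member_gene_ids),
        ct.EqtlSpec(h2_cis=0.7), 1, seed=303,
    )
    models = ct.filter_models(
        train_region_models(train, expr, catalog, region, seed=304, n_folds=5, n_alphas=15)
    )
    from collections import Counter

    winners = Counter()
    for seed in range(6):
        cohort = ct.simulate_genotype_panel(catalog, 800, seed=400 + seed, variants_per_gene=10)
        singles = {("C1", "T1"): prediction_frame(models, cohort, tissue_id="T1", pairs=False)}
        pairs = {("C1", "T1"): prediction_frame(models, cohort, tissue_id="T1", pairs=True)}
        spec = ct.EffectSpec(
            architecture="single_gene",
            target_gene_ids=[region.member_gene_ids[0]],
            effect_size=0.1,
        )
        pheno = ct.simulate_trait(cohort, expr.truth, spec, seed=500 + seed)
        rows = ct.tally_best_models(singles, pairs, {"C1": pheno}, region.region_id)
        winners.update(r.winner for r in rows)
    assert winners["single"] > winners["pairwise"]
    assert winners["single"] > winners["interaction"]
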