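"""Elastic-net trainer, pair targets, filtering."""

import numpy as np
import pytest

import cnvpairtwas as ct
from cnvpairtwas.exceptions import DegenerateInputError, ParameterError
from cnvpairtwas.expression_models import (
    WeightModel,
    make_pair_target,
    pair_unit_id,
    train_weight_model,
)


def test_pair_target_properties(rng):
    a = rng.standard_normal(100)
    b = rng.standard_normal(100)
    out = make_pair_target(a, b)
    assert abs(out.mean()) < 1e-8
    assert abs(out.std() - 1.0) < 0.1
    # rank transform ignores positive scaling: a+a has the ranks of a
    np.testing.assert_allclose(
        make_pair_target(a, a), ct.inverse_normal_transform(a)
    )
    with pytest.raises(DegenerateInputError):
        make_pair_target(a, -a)


def test_pair_unit_id_orders_by_genomic_position(universe):
    catalog, region = universe["catalog"], universe["region"]
    members = (
        catalog.subset(region.member_gene_ids)
        .genes.sort_values(["chrom", "start"])["gene_id"]
        .tolist()
    )
    assert pair_unit_id(members[3], members[0], catalog) == f"{members[0]}|{members[3]}"
    with pytest.raises(ParameterError):
        pair_unit_id(members[0], members[0], catalog)


def _train(dosages, target, panel, **kw):
    kw.setdefault("unit_id", "u")
    kw.setdefault("tissue_id", "T1")
    kw.setdefault("n_folds", 5)
    kw.setdefault("n_alphas", 15)
    return train_weight_model(dosages, target, panel.variants, **kw)


def test_trainer_recovers_exact_snp_target(universe):
    panel = universe["panel"]
    cols = panel.variants["variant_id"].iloc[:10].tolist()
    dosages = panel.dosage_frame(cols)
    target_col = dosages[cols[3]].to_numpy()
    target = (target_col - target_col.mean()) / target_col.std()
    model = _train(dosages, target, panel, seed=1)
    assert cols[3] in set(model.weights["variant_id"])
    assert model.cv_performance_r2 > 0.9
    assert model.n_snps_in_model == len(model.weights)


def test_trainer_is_deterministic_and_respects_allowlist(universe, rng):
    panel = universe["panel"]
    cols = panel.variants["variant_id"].iloc[:12].tolist()
    dosages = panel.dosage_frame(cols)
    target = dosages.to_numpy() @ rng.standard_normal(12) + rng.standard_normal(400)
    a = _train(dosages, target, panel, seed=7)
    b = _train(dosages, target, panel, seed=7)
    assert a.weights.equals(b.weights)

    allow = cols[:5]
    restricted = _train(dosages, target, panel, seed=7, snp_allowlist=allow)
    assert set(restricted.weights["variant_id"]) <= set(allow)


def test_trainer_edge_cases(universe):
    panel = universe["panel"]
    dosages = panel.dosage_frame(panel.variants["variant_id"].iloc[:4].tolist())
    with pytest.raises(ParameterError):
        _train(dosages.iloc[:3], np.zeros(3), panel, n_folds=5)
    empty = _train(dosages[[]], np.zeros(400), panel, seed=1)
    assert empty.is_empty and empty.cv_performance_r2 == 0.0


def test_null_targets_are_filtered_out(universe):
    """Noise targets should fail the PredictDB-style quality filter in
    nearly all replicates."""
    panel = universe["panel"]
    cols = panel.variants["variant_id"].iloc[:10].tolist()
    dosages = panel.dosage_frame(cols).iloc[:150]
    kept = 0
    n_reps = 40
    for rep in range(n_reps):
        noise = np.random.default_rng(1000 + rep).standard_normal(150)
        model = train_weight_model(
            dosages, noise, panel.variants, unit_id="null", tissue_id="T1",
            n_folds=5, seed=rep, n_alphas=10,
        )
        kept += bool(ct.filter_models([model]))
        assert model.cv_performance_r2 < 0.2
    assert kept <= int(0.15 * n_reps)


def test_filter_models_thresholds():
    def mk(r2, p):
        return WeightModel("u", "t", _one_weight(), r2, p)

    def _one_weight():
        import pandas as pd

        return pd.DataFrame(
            [("v", "G", "A", 0.5, 1.0, 0.5)],
            columns=["variant_id", "effect_allele", "ref_allele", "weight", "train_mean", "train_sd"],
        )

    models = [mk(0.2, 1e-5), mk(0.005, 0.3)]
    kept = ct.filter_models(models, 0.01, 0.05)
    assert [m.cv_performance_r2 for m in kept] == [0.2]
    assert ct.filter_models([], 0.01, 0.05) == []
    assert ct.filter_models(models, -1.0, 0.5) == models


def test_region_models_quality_and_allowlist(trained_models, universe):
    # every trained model's support lies inside the panel's variant set
    panel_vars = set(universe["panel"].variants["variant_id"])
    for m in trained_models:
        assert set(m.weights["variant_id"]) <= panel_vars
    singles = [m for m in trained_models if not m.is_pair]
    pairs = [m for m in trained_models if m.is_pair]
    assert len(singles) == 6 * 2  # genes x tissues
    assert len(pairs) == 15 * 2  # C(6,2) x tissues
    # at h2=0.5 the bulk of single models should carry real signal
    assert np.median([m.cv_performance_r2 for m in singles]) > 0.2
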