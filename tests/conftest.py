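"""Shared fixtures: one small synthetic universe reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import cnvpairtwas as ct


@pytest.fixture(scope="session")
def universe():
    """Catalog with a 6-gene CNV, a 400-sample panel, and 2-tissue
    expression at h2=0.5 — shared by read-only tests."""
    catalog, region = ct.generate_gene_catalog(
        60, ct.CnvSpec(n_genes=6, coding_fraction=0.75, length_bp=480_000), seed=101
    )
    panel = ct.simulate_genotype_panel(catalog, 400, seed=102, variants_per_gene=10)
    expr = ct.simulate_expression_panel(
        panel, catalog.subset(region.member_gene_ids), ct.EqtlSpec(h2_cis=0.5), 2, seed=103
    )
    return {"catalog": catalog, "region": region, "panel": panel, "expr": expr}


@pytest.fixture(scope="session")
def trained_models(universe):
    """Elastic-net models for the CNV region (singles + pairs)."""
    from cnvpairtwas.expression_models import train_region_models

    return train_region_models(
        universe["panel"],
        universe["expr"],
        universe["catalog"],
        universe["region"],
        seed=104,
        n_folds=5,
        n_alphas=15,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
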