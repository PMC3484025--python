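"""Shared fixtures: tiny hand-built inputs and the planted-enrichment
replicate sweep used by the statistical property tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from eqtlenrich import (
    EnrichmentConfig,
    EqtlEnrichment,
    GwasHitList,
    SimConfig,
    SnpUniverse,
    simulate_eqtl_map,
    simulate_gwas_hits,
    simulate_universe,
)


@pytest.fixture
def config() -> EnrichmentConfig:
    return EnrichmentConfig()


@pytest.fixture
def tiny_universe() -> SnpUniverse:
    """Ten SNPs spread over three MAF bins and two chromosomes."""
    frame = pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(1, 11)],
            "chrom": ["1", "1", "1", "1", "2", "2", "2", "2", "1", "2"],
            "pos": [
                1_000_000,
                2_000_000,
                5_000_000,
                80_000_000,
                1_000_000,
                3_000_000,
                90_000_000,
                150_000_000,
                200_000_000,
                200_000_000,
            ],
            "maf": [0.02, 0.03, 0.04, 0.01, 0.30, 0.32, 0.28, 0.26, 0.48, 0.50],
        }
    )
    return SnpUniverse(frame, platform_label="tiny")


@pytest.fixture
def tiny_eqtl() -> pd.DataFrame:
    """Raw eQTL rows for the tiny universe: significant cis (rs1, rs2),
    significant trans (rs5), a multi-gene SNP (rs1), and non-significant
    decoys (rs3 cis, rs6 trans)."""
    return pd.DataFrame(
        {
            "rsid": ["rs1", "rs1", "rs2", "rs5", "rs3", "rs6"],
            "tissue": ["parietal"] * 6,
            "gene": ["GENEA", "GENEB", "GENEA", "GENEC", "GENEA", "GENEC"],
            "probe_chrom": ["1", "1", "1", "7", "1", "9"],
            "probe_pos": [1_500_000, 4_000_000, 2_200_000, 5_000_000, 5_500_000, 999],
            "eqtl_p": [1e-6, 5e-5, 9e-5, 1e-7, 5e-4, 1e-5],
        }
    )


@pytest.fixture
def tiny_hits() -> GwasHitList:
    frame = pd.DataFrame(
        {"rsid": ["rs1", "rs3", "rs5", "rs9"], "gwas_p": [1e-5, 2e-4, 9e-4, 5e-4]}
    )
    return GwasHitList("Spec|All", frame)


def _one_replicate(theta: float, rep: int, n_sets: int = 500) -> float:
    """One synthetic dataset at planted enrichment ``theta`` -> empirical P.

    Study conditions of the statistical properties: 50,000-SNP universe,
    5% eQTL base rate, 500-SNP hit list, 500 null sets.
    """
    cfg = SimConfig(
        seed=rep + int(10_000 * theta),
        tissue_labels=("parietal",),
        analysis_labels=("sim",),
        enrichment_multiplier=theta,
    )
    universe = simulate_universe(cfg)
    eqtl_map = simulate_eqtl_map(universe, cfg)
    hits = simulate_gwas_hits(universe, eqtl_map, "parietal", cfg, analysis_label="sim")
    model = EqtlEnrichment(
        hits, eqtl_map.tables["parietal"], universe, tissue="parietal"
    )
    return model.fit(n_sets=n_sets, seed=rep).empirical_p


@pytest.fixture(scope="session")
def theta_sweep() -> dict:
    """Empirical P-values across 200 replicate synthetic datasets at
    planted enrichment multipliers 1 (null), 2 and 4."""
    n_reps = 200
    return {
        theta: np.array([_one_replicate(theta, rep) for rep in range(n_reps)])
        for theta in (1.0, 2.0, 4.0)
    }
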