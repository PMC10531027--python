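"""Shared fixtures: small simulated panels reused across test modules."""
from __future__ import annotations

import numpy as np
import pytest

from ricegwas.simdata import CausalSNP, SimConfig, simulate_genotypes, simulate_phenotype


@pytest.fixture(scope="session")
def small_panel():
    """200 accessions x 2x600 SNPs, no causal variants, no missing data."""
    cfg = SimConfig(n_accessions=200, n_chromosomes=2, snps_per_chromosome=600,
                    seed=42)
    G, labels = simulate_genotypes(cfg)
    return cfg, G, labels


@pytest.fixture(scope="session")
def causal_panel():
    """300 accessions with one planted causal SNP (h2_qtl=0.2, h2_poly=0.2)."""
    cfg = SimConfig(
        n_accessions=300, n_chromosomes=2, snps_per_chromosome=800,
        causal_snps=[CausalSNP("Chr1", 5_000_000, 15.0)],
        h2_qtl=0.2, h2_polygenic=0.2, replicate_sd=2.0, seed=7)
    G, labels = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotype(G, cfg, labels)
    return cfg, G, labels, pheno, truth


@pytest.fixture(scope="session")
def missing_panel():
    """Panel with 10% missing calls for QC and imputation paths."""
    cfg = SimConfig(n_accessions=150, n_chromosomes=1, snps_per_chromosome=400,
                    missing_rate=0.10, seed=3)
    G, labels = simulate_genotypes(cfg)
    return cfg, G, labels


@pytest.fixture
def rng():
    return np.random.default_rng(0)
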