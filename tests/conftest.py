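"""Shared fixtures: small panels and simulated studies built at test time."""

import numpy as np
import pytest

import multifinemap as mf


@pytest.fixture(scope="session")
def block_panel():
    """Two 10-SNP blocks with strong within-block LD."""
    return mf.make_block_panel(
        n_hap=5000, block_sizes=[10, 10], within_block_r=0.8, maf_range=(0.1, 0.4), seed=11
    )


@pytest.fixture(scope="session")
def indep_panel():
    """Six mutually independent SNPs."""
    return mf.make_block_panel(
        n_hap=2000, block_sizes=[1] * 6, within_block_r=0.0, maf_range=(0.15, 0.4), seed=12
    )


@pytest.fixture(scope="session")
def jointtag_trio():
    """Trio where snp3's minor allele tags two disjoint causal haplotypes.

    Mirrors the structure of real joint-tag examples: a common tag allele
    (MAF 0.4) carried together with either of two rarer causal minor alleles
    (MAF 0.15 each) that never co-occur.
    """
    r_cc = -0.0225 / 0.1275
    r_ct = 0.09 / np.sqrt(0.1275 * 0.24)
    return mf.embed_trio(0.15, 0.15, 0.4, r_cc, r_ct, r_ct, n_hap=20000)


@pytest.fixture(scope="session")
def single_causal_study(indep_panel):
    """One causal SNP (snp1, OR 1.4), 2000 cases vs 2000 controls."""
    geno = mf.sample_genotypes(indep_panel, 50000, 0.0, seed=21)
    spec = mf.SimulationSpec(
        causal_effects=(("snp1", 1, 1.4),), target_counts=(2000, 2000), seed=22
    )
    return mf.assign_multitrait(geno, indep_panel.snp_ids, spec)


@pytest.fixture(scope="session")
def two_disease_study(indep_panel):
    """Two diseases sharing causal snp1, plus snp3 specific to disease 2."""
    geno = mf.sample_genotypes(indep_panel, 60000, 0.0, seed=31)
    spec = mf.SimulationSpec(
        causal_effects=(("snp1", 1, 1.4), ("snp1", 2, 1.4), ("snp3", 2, 1.3)),
        target_counts=(1500, 1500, 1500),
        seed=32,
    )
    return mf.assign_multitrait(geno, indep_panel.snp_ids, spec)
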