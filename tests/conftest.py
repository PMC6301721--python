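"""Shared fixtures: toy exomes, rate tables and site catalogs are built once
per session (catalog construction enumerates every substitution and
dominates test time)."""

import numpy as np
import pytest

from dnvburden import mutation_model as mm
from dnvburden import synthetic_data as sd


@pytest.fixture(scope="session")
def uniform_rate_table():
    """All 192 entries at the same rate; trivially strand-symmetric."""
    u = 1e-6
    rates = {}
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                for alt in "ACGT":
                    if alt != b:
                        rates[(a + b + c, a + alt + c)] = u
    return mm.RateTable(rates), u


@pytest.fixture(scope="session")
def small_cfg():
    return sd.GeneratorConfig(seed=11, n_genes=40, cds_len_mean=600,
                              n_trios=300, frac_two_exon=0.4, frac_chrx=0.1)


@pytest.fixture(scope="session")
def small_exome(small_cfg):
    return sd.gen_exome(small_cfg)


@pytest.fixture(scope="session")
def small_rate_table(small_cfg):
    return sd.gen_rate_table(small_cfg)


@pytest.fixture(scope="session")
def small_catalog(small_exome, small_rate_table):
    return sd.SiteCatalog.build(small_exome, small_rate_table)


@pytest.fixture(scope="session")
def small_rates(small_exome, small_rate_table, small_cfg):
    return {g.gene: mm.gene_class_rates(g, small_exome.genome, small_rate_table,
                                        small_cfg.dmis_fraction)
            for g in small_exome.genes}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
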