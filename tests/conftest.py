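from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from macrna.synthdata import (GeneratorConfig, gen_genome, gen_micro_locus,
                              gen_ncrna_decoys, gen_small_rna_pool)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """A small mating-mode universe: 12 nanochromosomes, ~150 reads each."""
    return GeneratorConfig(seed=7, n_nano=12, reads_per_nano_mean=150,
                           nano_len_mean=1500, nano_len_sd=300)


@pytest.fixture(scope="session")
def small_genes(small_cfg):
    return gen_genome(small_cfg, small_cfg.rng())


@pytest.fixture(scope="session")
def small_bundle(small_cfg, small_genes):
    """(genes, loci, decoys, pool) generated from one seeded stream."""
    rng = np.random.default_rng(99)
    loci = [gen_micro_locus(g, 4, scrambled=(i % 3 == 0), rng=rng)
            for i, g in enumerate(small_genes)]
    decoys = gen_ncrna_decoys(small_cfg, rng)
    pool = gen_small_rna_pool(small_genes, loci, small_cfg, rng, decoys=decoys)
    return small_genes, loci, decoys, pool
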