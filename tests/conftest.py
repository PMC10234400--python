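"""Shared fixtures: small synthetic trials reused across test modules."""
import numpy as np
import pandas as pd
import pytest

from metgs import GenomicModelConfig, simulate_markers, simulate_phenotypes
from metgs.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_trial():
    """Two populations x 20/25 clones, 2 locations x 4 years, 3 blocks."""
    cfg = SimulationConfig(
        n_genotypes_per_pop=(20, 25),
        n_markers=120,
        seed=7,
        missing_rate=0.05,
    )
    markers = simulate_markers(cfg)
    pheno, truth = simulate_phenotypes(markers, cfg)
    return cfg, markers, pheno, truth


@pytest.fixture(scope="session")
def noiseless_trial():
    """Purely additive noiseless trial: value = mu + g + h + block exactly."""
    cfg = SimulationConfig(
        n_genotypes_per_pop=12,
        n_pops=1,
        n_markers=60,
        seed=3,
        gxe_rank=0,
        fw_slope_sd=0.0,
        residual_sd=0.0,
        missing_rate=0.0,
    )
    markers = simulate_markers(cfg)
    pheno, truth = simulate_phenotypes(markers, cfg)
    return cfg, markers, pheno, truth


@pytest.fixture
def quick_chain():
    """Short sampler settings for unit tests (defaults mirror the full study)."""
    return GenomicModelConfig(n_iter=1500, burn_in=500, thin=2, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_two_way(rng, g=10, e=6, interaction_scale=1.0):
    """Random complete genotype x environment table of cell means."""
    from metgs.stability import TwoWayTable

    mu = 10.0
    gi = rng.normal(0, 1, g)
    ej = rng.normal(0, 1, e)
    z = rng.normal(0, interaction_scale, (g, e))
    vals = mu + gi[:, None] + ej[None, :] + z
    return TwoWayTable(
        vals, [f"g{i + 1:02d}" for i in range(g)], [f"e{j + 1:02d}" for j in range(e)]
    )
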