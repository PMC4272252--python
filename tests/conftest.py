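"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from parscout import linkage as lk
from parscout.sim import SimConfig, simulate_pedigree, simulate_zw_genotypes
from parscout.sim.config import Scaffold


TINY_PLAN = (
    Scaffold("auto_1", 500_000, "autosome"),
    Scaffold("par_1", 400_000, "PAR"),
    Scaffold("zdiff_1", 600_000, "Z_diff"),
)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return SimConfig(
        seed=11,
        n_families=5,
        offspring_per_family=8,
        n_generations=3,
        genome_plan=TINY_PLAN,
        marker_spacing=50_000,
    )


@pytest.fixture(scope="session")
def linkage_cohort():
    """~500 meioses per sex: 20 two-generation families of 25 offspring."""
    config = SimConfig(
        seed=23,
        n_families=20,
        offspring_per_family=25,
        n_generations=2,
        genome_plan=TINY_PLAN,
        marker_spacing=50_000,
    )
    ped = simulate_pedigree(config)
    gt, truth = simulate_zw_genotypes(ped, config)
    ts = lk.resolve_transmissions(gt, ped)
    return config, ped, gt, truth, ts


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
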