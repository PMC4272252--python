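"""Sex-pooled per-base sequencing depth simulation.

Each individual contributes reads at a per-base rate proportional to its
copy number: 2 for autosomes and the PAR in both sexes and for the
differentiated Z in males, 1 for the differentiated Z in females.  Pooling
independent Poisson individuals gives a Poisson pool, so pools are drawn
directly at the summed rate; a negative-binomial option adds overdispersion
(var = mu + dispersion * mu^2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._util import stage_rng
from .config import ROLE_Z_DIFF, SimConfig


def expected_pool_depth(config: SimConfig, role: str, sex: str) -> float:
    """Expected pooled reads per base for a scaffold role and sex pool."""
    n = config.n_males if sex == "M" else config.n_females
    copies = 1 if (role == ROLE_Z_DIFF and sex == "F") else 2
    return n * config.depth_mean * copies / 2.0


def _draw(rng: np.random.Generator, mu: float, size: int, model: str, dispersion: float) -> np.ndarray:
    if model == "poisson" or dispersion <= 0:
        return rng.poisson(mu, size)
    # NB as gamma-mixed Poisson: shape r = 1/dispersion, mean mu
    r = 1.0 / dispersion
    lam = rng.gamma(r, mu / r, size)
    return rng.poisson(lam)


def simulate_read_depth(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-base pooled depth table: scaffold, pos (1-based), depth_M, depth_F."""
    if rng is None:
        rng = stage_rng(config.seed, "depth")
    frames = []
    for scaf in config.genome_plan:
        n = scaf.length
        depth_m = _draw(
            rng, expected_pool_depth(config, scaf.role, "M"), n, config.depth_model, config.depth_dispersion
        )
        depth_f = _draw(
            rng, expected_pool_depth(config, scaf.role, "F"), n, config.depth_model, config.depth_dispersion
        )
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaf.name,
                    "pos": np.arange(1, n + 1, dtype=np.int64),
                    "depth_M": depth_m.astype(np.int64),
                    "depth_F": depth_f.astype(np.int64),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_depth_tsv(depth: pd.DataFrame, path) -> None:
    depth.to_csv(path, sep="\t", index=False)


def read_depth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"scaffold": str})
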