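"""Two-species, two-sex phased haplotype panel with controlled diversity and LD.

The generator is a blockwise ancestor-copying model rather than a coalescent:
each scaffold is partitioned by a stationary renewal process of segment
boundaries whose lengths follow a Lomax distribution with shape 2 and mean
1/alpha, which makes the probability that two positions at distance d fall in
the same segment exactly 1/(1 + alpha d) — the LD decay curve the downstream
fit assumes.  Within a segment every haplotype belongs to one of two local
lineages (frequency u ~ Uniform(0,1) drawn per segment), and every
polymorphic site in the segment separates the same two lineages, so
within-segment r^2 is 1 and between-segment r^2 is sampling noise.

Polymorphic-site density is 3 x pi_target per bp: with u uniform the expected
per-site heterozygosity contribution is E[2u(1-u)] = 1/3, making realized
diversity unbiased for the target.  Fixed inter-species differences are
placed at df_target per bp.  The alternate allele is always assigned to the
minor lineage so that low-frequency variants cannot masquerade as fixed
differences in finite samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._util import stage_rng
from ..popgen import MISSING, HaplotypePanel
from .config import ROLE_Z_DIFF, SimConfig


def lomax_segment_breakpoints(length: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Interior segment boundaries of the stationary Lomax(2, 1/alpha) renewal process."""
    if alpha <= 0:
        return np.array([])
    bps = []
    # first boundary: equilibrium residual length, CDF 1 - (1 + alpha y)^-1
    x = (1.0 / rng.random() - 1.0) / alpha
    while x < length:
        bps.append(x)
        # subsequent lengths: Lomax shape 2, CDF 1 - (1 + alpha x)^-2
        x += ((1.0 - rng.random()) ** -0.5 - 1.0) / alpha
    return np.asarray(bps)


def _polymorphic_block(
    length: int, pi: float, alpha: float, n_hap: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Positions (0-based float) and (n_hap x n_sites) allele matrix for one species."""
    n_sites = rng.poisson(3.0 * pi * length)
    if n_sites == 0:
        return np.array([]), np.zeros((n_hap, 0), dtype=np.int8)
    pos = np.sort(rng.uniform(0, length, n_sites))
    if alpha > 0:
        bps = lomax_segment_breakpoints(length, alpha, rng)
        seg = np.searchsorted(bps, pos)
        n_seg = len(bps) + 1
    else:  # no decay: a single segment, complete linkage
        seg = np.zeros(n_sites, dtype=int)
        n_seg = 1
    u = rng.uniform(0, 1, n_seg)
    lineage = (rng.random((n_hap, n_seg)) < u).astype(np.int8)
    alleles = lineage[:, seg]
    flip = u[seg] > 0.5  # alt allele = minor lineage
    return pos, np.where(flip, 1 - alleles, alleles).astype(np.int8)


def simulate_haplotypes(
    config: SimConfig,
    scaffolds: tuple[str, ...] | None = None,
    rng: np.random.Generator | None = None,
) -> HaplotypePanel:
    """Panel of two species ("A", "B"), each with male and female pools.

    By default covers the Z scaffolds (PAR + differentiated), where females
    carry a single allele copy outside the PAR; autosomal scaffolds from the
    genome plan may be requested as well.
    """
    if rng is None:
        rng = stage_rng(config.seed, "haplotypes")
    plan = {s.name: s for s in config.genome_plan}
    if scaffolds is None:
        scaffolds = tuple(s.name for s in config.z_scaffold_order())
    for name in scaffolds:
        if name not in plan:
            raise KeyError(f"scaffold {name!r} not in genome plan")

    n_per_sex = config.n_haplotype_individuals
    individuals = pd.DataFrame(
        [
            {"id": f"{sp}_{sex}{i + 1:02d}", "species": sp, "sex": sex}
            for sp in ("A", "B")
            for sex in ("M", "F")
            for i in range(n_per_sex)
        ]
    )
    n_ind = len(individuals)

    site_frames = []
    allele_blocks = []
    ploidy_cols = {}
    for name in scaffolds:
        scaf = plan[name]
        pi = config.pi_target[scaf.role]
        df = config.df_target[scaf.role]
        alpha = config.alpha_ld[scaf.role]
        female_haploid = scaf.role == ROLE_Z_DIFF

        entries: list[tuple[float, str, np.ndarray | None]] = []
        for sp in ("A", "B"):
            n_hap = _haplotype_count(individuals, sp, female_haploid, n_per_sex)
            pos, alle = _polymorphic_block(scaf.length, pi, alpha, n_hap, rng)
            for k in range(len(pos)):
                entries.append((pos[k], sp, alle[:, k]))
        n_fixed = rng.poisson(df * scaf.length)
        for p in rng.uniform(0, scaf.length, n_fixed):
            entries.append((float(p), "fixed", None))

        entries.sort(key=lambda e: e[0])
        block = np.zeros((n_ind, 2, len(entries)), dtype=np.int8)
        positions = np.empty(len(entries), dtype=np.int64)
        last = 0
        for k, (p, kind, alle) in enumerate(entries):
            # integer 1-based positions, strictly increasing
            positions[k] = max(int(p) + 1, last + 1)
            last = positions[k]
            if kind == "fixed":
                block[(individuals["species"] == "B").to_numpy(), :, k] = 1
            else:
                sp_mask = (individuals["species"] == kind).to_numpy()
                block[sp_mask, :, k] = _fold_haplotypes(alle, sp_mask.sum(), female_haploid, individuals[sp_mask])
        if female_haploid:
            fem = (individuals["sex"] == "F").to_numpy()
            block[fem, 1, :] = MISSING
        site_frames.append(
            pd.DataFrame(
                {"scaffold": name, "position": positions, "ref": "A", "alt": "T"}
            )
        )
        allele_blocks.append(block)
        ploidy_cols[name] = np.where(
            (individuals["sex"] == "F") & female_haploid, 1, 2
        )

    sites = pd.concat(site_frames, ignore_index=True)
    alleles = np.concatenate(allele_blocks, axis=2) if allele_blocks else np.zeros((n_ind, 2, 0), np.int8)
    ploidy = pd.DataFrame(ploidy_cols, index=individuals["id"])
    return HaplotypePanel(sites=sites, alleles=alleles, individuals=individuals, ploidy=ploidy)


def _haplotype_count(individuals: pd.DataFrame, species: str, female_haploid: bool, n_per_sex: int) -> int:
    if female_haploid:
        return 2 * n_per_sex + n_per_sex  # 2 per male, 1 per female
    return 4 * n_per_sex


def _fold_haplotypes(
    alle: np.ndarray, n_sp_ind: int, female_haploid: bool, sub: pd.DataFrame
) -> np.ndarray:
    """Distribute a flat haplotype vector onto (individual, copy) slots."""
    out = np.zeros((n_sp_ind, 2), dtype=np.int8)
    cursor = 0
    sexes = sub["sex"].to_numpy()
    for i in range(n_sp_ind):
        copies = 1 if (female_haploid and sexes[i] == "F") else 2
        out[i, :copies] = alle[cursor : cursor + copies]
        cursor += copies
    return out
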