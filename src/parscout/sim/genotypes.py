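"""ZW gamete transmission and marker genotype simulation.

The Z chromosome is modelled as its PAR scaffolds (terminal, chromosome
start) followed by the differentiated scaffolds.  Female meiosis performs at
most one Z-W crossover, obligate in the sense that exactly half of all
gametes are recombinant (one crossover on two of the four chromatids), with
the crossover position drawn from a piecewise-constant intensity: a hotspot
interval absorbing a configured fraction of events, uniform background over
the rest of the PAR.  Males recombine along the whole chromosome with
independent Poisson crossovers.  Females carry a single Z, so their
differentiated-Z genotypes are hemizygous; their W contributes the second
PAR allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._util import marker_id, stage_rng
from .config import ROLE_AUTOSOME, SimConfig
from .pedigree import MISSING_PARENT, Pedigree

MISSING_ALLELE = -1
_ALLELE_CHARS = np.array(["A", "B"])


class InputError(ValueError):
    pass


@dataclass
class GenotypeTable:
    """Biallelic marker calls for a cohort.

    ``calls`` holds one string per marker x individual: 'AA'/'AB'/'BB' for
    diploid sites, 'A'/'B' for hemizygous ones, '.' for missing.  Marker
    metadata carries the scaffold role so downstream code can respect female
    hemizygosity on the differentiated Z.
    """

    markers: pd.DataFrame  # marker, scaffold, position, role, chrom, chrom_pos
    calls: pd.DataFrame  # index: marker id; columns: individual ids

    def __post_init__(self) -> None:
        if list(self.calls.index) != list(self.markers["marker"]):
            raise ValueError("calls index must match marker order")

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.columns)

    def role_of(self, marker: str) -> str:
        return self._meta.at[marker, "role"]

    @property
    def _meta(self) -> pd.DataFrame:
        if not hasattr(self, "_meta_cache"):
            object.__setattr__(self, "_meta_cache", self.markers.set_index("marker"))
        return self._meta_cache


def build_marker_table(config: SimConfig) -> pd.DataFrame:
    """Array-like marker grid: one marker every ``marker_spacing`` bp.

    ``chrom`` groups scaffolds into linkage units (each autosomal scaffold its
    own unit; all Z scaffolds share unit 'Z'); ``chrom_pos`` is the 0-based
    coordinate on that unit used for recombination.
    """
    z_offsets = config.z_offsets()
    rows = []
    for scaf in config.genome_plan:
        positions = np.arange(config.marker_spacing // 2, scaf.length + 1, config.marker_spacing)
        for pos in positions:  # 1-based scaffold coordinate
            pos = int(pos)
            if scaf.role == ROLE_AUTOSOME:
                chrom, cpos = scaf.name, pos - 1
            else:
                chrom, cpos = "Z", z_offsets[scaf.name] + pos - 1
            rows.append((marker_id(scaf.name, pos), scaf.name, pos, scaf.role, chrom, cpos))
    table = pd.DataFrame(rows, columns=["marker", "scaffold", "position", "role", "chrom", "chrom_pos"])
    return table.sort_values(["chrom", "chrom_pos"], kind="stable").reset_index(drop=True)


def sample_female_crossovers(
    config: SimConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` female Z-W meiotic outcomes.

    Returns (recombinant flags, crossover positions); positions are NaN for
    the non-recombinant half and otherwise drawn from the hotspot-weighted
    intensity over the PAR.
    """
    recomb = rng.random(n) < 0.5
    pos = np.full(n, np.nan)
    k = int(recomb.sum())
    hs = config.effective_hotspot()
    in_hot = rng.random(k) < hs.fraction
    hot = rng.uniform(hs.start, hs.end, k)
    # background: uniform over the PAR outside the hotspot interval
    bg_len = config.par_length - (hs.end - hs.start)
    if bg_len > 0:
        raw = rng.uniform(0, bg_len, k)
        cold = np.where(raw < hs.start, raw, raw + (hs.end - hs.start))
    else:
        cold = hot
    pos[recomb] = np.where(in_hot, hot, cold)
    return recomb, pos


def _male_breakpoints(config: SimConfig, length_bp: int, rng: np.random.Generator) -> np.ndarray:
    expected = (config.male_co_rate / 100.0) * length_bp / 1e6  # crossovers per gamete
    k = rng.poisson(expected)
    return np.sort(rng.uniform(0, length_bp, k))


def _gamete(haps: np.ndarray, positions: np.ndarray, breakpoints: np.ndarray, start: int) -> np.ndarray:
    """Transmit a mosaic of the two parental haplotypes.

    ``haps`` is (2, n_markers); the transmitted haplotype index flips at each
    breakpoint, beginning from ``start``.
    """
    seg = np.searchsorted(breakpoints, positions, side="right")
    return haps[(start + seg) % 2, np.arange(haps.shape[1])]


@dataclass
class _ZMeiosisLog:
    """Realized crossover breakpoints per transmitted Z/W product, for truth maps."""

    sex: str  # of the transmitting parent
    breakpoints: np.ndarray
    covers_zdiff: bool  # False for maternal W products (PAR-only)


def simulate_zw_genotypes(
    ped: Pedigree, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Drop founder haplotypes and transmit through the pedigree.

    Returns the genotype table and a truth map recording, for each adjacent
    Z-marker interval, the realized recombinant fraction in female and male
    meioses (NaN where no informative transmissions exist).
    """
    if rng is None:
        rng = stage_rng(config.seed, "genotypes")
    markers = build_marker_table(config)
    units = {chrom: grp for chrom, grp in markers.groupby("chrom", sort=False)}
    unit_positions = {chrom: grp["chrom_pos"].to_numpy() for chrom, grp in units.items()}
    unit_lengths = {}
    for scaf in config.scaffolds(ROLE_AUTOSOME):
        unit_lengths[scaf.name] = scaf.length
    unit_lengths["Z"] = config.z_length

    z_pos = unit_positions.get("Z", np.array([], dtype=int))
    par_len = config.par_length

    genomes: dict[str, dict[str, np.ndarray]] = {}
    z_logs: list[tuple[_ZMeiosisLog, np.ndarray]] = []  # log + transmitted-site mask

    order = ped.table.sort_values(["generation"], kind="stable")
    for _, row in order.iterrows():
        ind, sex = row["id"], row["sex"]
        genome: dict[str, np.ndarray] = {}
        founder = row["sire"] == MISSING_PARENT
        for chrom, positions in unit_positions.items():
            n = len(positions)
            if founder:
                haps = rng.integers(0, 2, size=(2, n)).astype(np.int8)
                if chrom == "Z" and sex == "F":
                    # single Z plus a W that is PAR-homologous only
                    haps[1, positions >= par_len] = MISSING_ALLELE
            else:
                sire_h, dam_h = genomes[row["sire"]][chrom], genomes[row["dam"]][chrom]
                if chrom != "Z":
                    paternal = _gamete(
                        sire_h, positions, _male_breakpoints(config, unit_lengths[chrom], rng), rng.integers(0, 2)
                    )
                    maternal = _gamete(
                        dam_h, positions, _male_breakpoints(config, unit_lengths[chrom], rng), rng.integers(0, 2)
                    )
                    haps = np.stack([paternal, maternal])
                else:
                    bp = _male_breakpoints(config, unit_lengths["Z"], rng)
                    paternal = _gamete(sire_h, positions, bp, rng.integers(0, 2))
                    z_logs.append((_ZMeiosisLog("M", bp, True), np.ones(n, bool)))
                    maternal, log, mask = _female_z_product(dam_h, positions, par_len, sex, config, rng)
                    z_logs.append((log, mask))
                    haps = np.stack([paternal, maternal])
                    if sex == "F":
                        haps[1, positions >= par_len] = MISSING_ALLELE
            genome[chrom] = haps
        genomes[ind] = genome

    calls = _emit_calls(markers, units, genomes, ped)
    truth = _truth_map(markers, z_pos, z_logs, par_len)
    return GenotypeTable(markers, calls), truth


def _female_z_product(
    dam_h: np.ndarray,
    positions: np.ndarray,
    par_len: int,
    child_sex: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, _ZMeiosisLog, np.ndarray]:
    """One maternal Z-W meiotic product, conditioned on the child's sex.

    Sons receive the product whose differentiated tail is the maternal Z;
    daughters receive the W-tailed product (differentiated sites absent).
    """
    recomb, xs = sample_female_crossovers(config, 1, rng)
    z_row, w_row = dam_h[0], dam_h[1]
    if child_sex == "M":
        if recomb[0]:
            x = xs[0]
            product = np.where(positions < x, w_row, z_row)
            bp = np.array([x])
        else:
            product = z_row.copy()
            bp = np.array([])
        mask = np.ones(len(positions), bool)
        return product, _ZMeiosisLog("F", bp, True), mask
    if recomb[0]:
        x = xs[0]
        product = np.where(positions < x, z_row, w_row)
        bp = np.array([x])
    else:
        product = w_row.copy()
        bp = np.array([])
    mask = positions < par_len  # W product carries no differentiated-Z markers
    return product, _ZMeiosisLog("F", bp, False), mask


def _emit_calls(
    markers: pd.DataFrame,
    units: dict[str, pd.DataFrame],
    genomes: dict[str, dict[str, np.ndarray]],
    ped: Pedigree,
) -> pd.DataFrame:
    columns = {}
    for ind in ped.ids:
        parts = []
        for chrom, grp in units.items():
            haps = genomes[ind][chrom]
            strings = np.empty(len(grp), dtype=object)
            hemi = haps[1] == MISSING_ALLELE
            lo = np.minimum(haps[0], np.where(hemi, haps[0], haps[1]))
            hi = np.maximum(haps[0], np.where(hemi, haps[0], haps[1]))
            diploid = np.char.add(_ALLELE_CHARS[lo], _ALLELE_CHARS[hi])
            strings[~hemi] = diploid[~hemi]
            strings[hemi] = _ALLELE_CHARS[haps[0][hemi]]
            parts.append(pd.Series(strings, index=grp["marker"].to_numpy()))
        columns[ind] = pd.concat(parts)
    calls = pd.DataFrame(columns).reindex(markers["marker"].to_numpy())
    calls.index.name = "marker"
    return calls


def _truth_map(
    markers: pd.DataFrame, z_pos: np.ndarray, z_logs: list, par_len: int
) -> pd.DataFrame:
    """Realized per-interval recombinant fractions on the Z, by parental sex."""
    z_markers = markers[markers["chrom"] == "Z"].reset_index(drop=True)
    n = len(z_markers)
    rec = {"F": np.zeros(max(n - 1, 0)), "M": np.zeros(max(n - 1, 0))}
    tot = {"F": np.zeros(max(n - 1, 0)), "M": np.zeros(max(n - 1, 0))}
    for log, mask in z_logs:
        if n < 2:
            break
        crossings = np.searchsorted(log.breakpoints, z_pos, side="right")
        odd = (np.diff(crossings) % 2).astype(bool)
        informative = mask[:-1] & mask[1:]
        tot[log.sex][informative] += 1
        rec[log.sex][informative & odd] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_f = np.where(tot["F"] > 0, rec["F"] / np.maximum(tot["F"], 1), np.nan)
        theta_m = np.where(tot["M"] > 0, rec["M"] / np.maximum(tot["M"], 1), np.nan)

    def _cum(theta: np.ndarray) -> np.ndarray:
        t = np.nan_to_num(np.clip(theta, 0, 0.4999999), nan=0.0)
        d = -50.0 * np.log1p(-2.0 * t)  # Haldane, cM
        return np.concatenate([[0.0], np.cumsum(d)])

    out = z_markers[["marker", "scaffold", "position", "role", "chrom_pos"]].copy()
    out["theta_f"] = np.append(theta_f, np.nan) if n else []
    out["theta_m"] = np.append(theta_m, np.nan) if n else []
    out["n_f"] = np.append(tot["F"], 0) if n else []
    out["n_m"] = np.append(tot["M"], 0) if n else []
    out["cum_cM_f"] = _cum(theta_f) if n else []
    out["cum_cM_m"] = _cum(theta_m) if n else []
    return out
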