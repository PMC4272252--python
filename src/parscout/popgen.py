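"""Ploidy-aware windowed population-genomic statistics.

All estimators operate on a :class:`HaplotypePanel` of phased biallelic
haplotypes in which each individual carries, per scaffold, either one or two
allele copies.  This matters on a differentiated Z chromosome: females are
hemizygous outside the PAR, so site allele counts — and therefore nucleotide
diversity, FST and LD — must be computed from the actual number of sampled
chromosomes rather than from an assumed diploid genotype.

Statistics implemented:

* per-site unbiased nucleotide diversity pi = sum_s [n/(n-1)] 2 p (1-p)
  averaged over callable sites;
* FST between two groups, either Weir–Cockerham variance components on
  allele counts (ratio of sums over sites; default, robust to mixed ploidy)
  or Hudson's 1 - Hw/Hb;
* density of fixed inter-group differences d_f;
* pairwise LD r^2 on phased haplotypes and the decay fit
  E(r^2) = 1/(1 + alpha d), with d01 = 9/alpha the distance at which the
  expected r^2 falls to 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

MISSING = -1


class UndefinedStatistic(ValueError):
    """A statistic has no defined value for the requested data (not an error state)."""


# --------------------------------------------------------------------------
# container
# --------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes with per-individual, per-scaffold ploidy.

    ``alleles`` has shape (n_individuals, 2, n_sites) with entries 0 (ref),
    1 (alt) or -1 where an individual carries fewer than two copies.
    ``sites`` columns: scaffold, position (1-based), ref, alt.
    ``individuals`` columns: id, species, sex.
    ``ploidy`` maps individual id x scaffold -> {1, 2}.
    """

    sites: pd.DataFrame
    alleles: np.ndarray
    individuals: pd.DataFrame
    ploidy: pd.DataFrame

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)
        n_ind, two, n_sites = self.alleles.shape
        if two != 2 or n_ind != len(self.individuals) or n_sites != len(self.sites):
            raise ValueError("alleles shape must be (n_individuals, 2, n_sites)")
        pos = self.sites.groupby("scaffold")["position"]
        if not all(g.is_monotonic_increasing and g.is_unique for _, g in pos):
            raise ValueError("site positions must be strictly increasing per scaffold")

    def mask(self, group: dict | None) -> np.ndarray:
        """Boolean individual mask from e.g. ``{"species": "A"}`` or ``{"sex": "F"}``."""
        m = np.ones(len(self.individuals), dtype=bool)
        for key, value in (group or {}).items():
            m &= (self.individuals[key] == value).to_numpy()
        if group and not m.any():
            raise KeyError(f"no individuals match {group!r}")
        return m

    def site_selector(self, scaffold: str | None = None, start: int | None = None, end: int | None = None) -> np.ndarray:
        """Site mask for a 0-based half-open window on one scaffold."""
        m = np.ones(len(self.sites), dtype=bool)
        if scaffold is not None:
            m &= (self.sites["scaffold"] == scaffold).to_numpy()
        p0 = self.sites["position"].to_numpy() - 1  # internal 0-based
        if start is not None:
            m &= p0 >= start
        if end is not None:
            m &= p0 < end
        return m

    def allele_counts(self, group: dict | None = None, sites: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(alt count, total non-missing alleles) per selected site in a group."""
        ind = self.mask(group)
        a = self.alleles[ind][:, :, sites if sites is not None else slice(None)]
        flat = a.reshape(2 * int(ind.sum()), a.shape[-1])
        present = flat != MISSING
        return (flat == 1).sum(axis=0), present.sum(axis=0)

    def haplotype_rows(self, group: dict | None = None, sites: np.ndarray | None = None) -> np.ndarray:
        """Phased haplotype matrix for sites of uniform ploidy (all-missing rows dropped)."""
        ind = self.mask(group)
        a = self.alleles[ind][:, :, sites if sites is not None else slice(None)]
        rows = a.reshape(2 * int(ind.sum()), a.shape[-1])
        if rows.shape[1] == 0:
            return rows[:0]
        keep = ~(rows == MISSING).all(axis=1)
        rows = rows[keep]
        if (rows == MISSING).any():
            raise ValueError("sites of mixed ploidy cannot form a haplotype matrix")
        return rows


# --------------------------------------------------------------------------
# scalar statistics
# --------------------------------------------------------------------------


def nucleotide_diversity(
    panel: HaplotypePanel,
    group: dict | None = None,
    scaffold: str | None = None,
    start: int | None = None,
    end: int | None = None,
    callable_length: int | None = None,
) -> float:
    """Mean pairwise diversity per callable site over a window.

    Sites with fewer than two sampled alleles are skipped.  The denominator is
    ``callable_length`` when given, otherwise the window (or scaffold-subset)
    span; monomorphic non-listed positions are assumed callable.
    """
    sites = panel.site_selector(scaffold, start, end)
    length = _resolve_length(panel, sites, scaffold, start, end, callable_length)
    return _pi_from_sites(panel, group, sites, length)


def _pi_from_sites(panel: HaplotypePanel, group: dict | None, sites: np.ndarray, length: int) -> float:
    if length <= 0:
        raise UndefinedStatistic("window has no callable sites")
    alt, tot = panel.allele_counts(group, sites)
    usable = tot >= 2
    alt, tot = alt[usable], tot[usable]
    with np.errstate(invalid="ignore"):
        p = alt / tot
        h = tot / (tot - 1) * 2.0 * p * (1.0 - p)
    return float(h.sum() / length)


def _resolve_length(panel, sites, scaffold, start, end, callable_length) -> int:
    if callable_length is not None:
        return callable_length
    if start is not None and end is not None:
        return end - start
    if scaffold is not None:
        pos = panel.sites.loc[sites, "position"]
        return int(pos.max()) if len(pos) else 0
    raise UndefinedStatistic("cannot infer callable length; pass callable_length")


def hudson_fst(
    panel: HaplotypePanel, group_a: dict, group_b: dict, sites: np.ndarray | None = None
) -> float:
    """Hudson's FST = 1 - Hw/Hb, as a ratio of sums over sites.

    The plug-in form (Hw = mean of 2p(1-p) across the two groups) is used,
    so identical sample frequencies give exactly 0 and a fixed difference
    exactly 1 — the closed-form behavior the tests pin down.  The default
    Weir-Cockerham estimator is the one with finite-sample bias correction.
    """
    alt_a, tot_a = panel.allele_counts(group_a, sites)
    alt_b, tot_b = panel.allele_counts(group_b, sites)
    ok = (tot_a >= 2) & (tot_b >= 2)
    if not ok.any():
        raise UndefinedStatistic("no sites with two alleles sampled in both groups")
    pa, pb = alt_a[ok] / tot_a[ok], alt_b[ok] / tot_b[ok]
    hw = (2 * pa * (1 - pa) + 2 * pb * (1 - pb)) / 2.0
    hb = pa * (1 - pb) + pb * (1 - pa)
    poly = (hw > 0) | (hb > 0)
    if not poly.any() or hb[poly].sum() == 0:
        raise UndefinedStatistic("no polymorphic sites in the union of the groups")
    return float(1.0 - hw[poly].sum() / hb[poly].sum())


def weir_cockerham_fst(
    panel: HaplotypePanel, group_a: dict, group_b: dict, sites: np.ndarray | None = None
) -> float:
    """Weir–Cockerham theta on allele counts, ratio of sums over sites.

    The allele-level (haploid-observation) form of the variance-components
    estimator is used so that mixed-ploidy regions — diploid PAR alongside
    hemizygous female Z — contribute each sampled chromosome exactly once.
    """
    alt_a, tot_a = panel.allele_counts(group_a, sites)
    alt_b, tot_b = panel.allele_counts(group_b, sites)
    ok = (tot_a >= 2) & (tot_b >= 2)
    if not ok.any():
        raise UndefinedStatistic("no sites with two alleles sampled in both groups")
    n1, n2 = tot_a[ok].astype(float), tot_b[ok].astype(float)
    p1, p2 = alt_a[ok] / n1, alt_b[ok] / n2
    n = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / n
    r = 2
    msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n - r)
    nc = (n - (n1**2 + n2**2) / n) / (r - 1)
    num = (msp - msg).sum()
    den = (msp + (nc - 1) * msg).sum()
    if den == 0:
        raise UndefinedStatistic("no variance at any site")
    return float(num / den)


def fst(
    panel: HaplotypePanel,
    group_a: dict,
    group_b: dict,
    scaffold: str | None = None,
    start: int | None = None,
    end: int | None = None,
    estimator: str = "weir-cockerham",
) -> float:
    sites = panel.site_selector(scaffold, start, end)
    if estimator == "weir-cockerham":
        return weir_cockerham_fst(panel, group_a, group_b, sites)
    if estimator == "hudson":
        return hudson_fst(panel, group_a, group_b, sites)
    raise ValueError(f"unknown FST estimator {estimator!r}")


def fixed_difference_density(
    panel: HaplotypePanel,
    species_a: dict,
    species_b: dict,
    scaffold: str | None = None,
    start: int | None = None,
    end: int | None = None,
    callable_length: int | None = None,
) -> float:
    """Fraction of callable sites at which the two groups share no allele."""
    sites = panel.site_selector(scaffold, start, end)
    length = _resolve_length(panel, sites, scaffold, start, end, callable_length)
    if length <= 0:
        raise UndefinedStatistic("zero-length window")
    alt_a, tot_a = panel.allele_counts(species_a, sites)
    alt_b, tot_b = panel.allele_counts(species_b, sites)
    ok = (tot_a >= 1) & (tot_b >= 1)
    fixed_alt_a = ok & (alt_a == tot_a) & (alt_b == 0)
    fixed_alt_b = ok & (alt_a == 0) & (alt_b == tot_b)
    return float((fixed_alt_a | fixed_alt_b).sum() / length)


# --------------------------------------------------------------------------
# linkage disequilibrium
# --------------------------------------------------------------------------


def r2_matrix_pairs(rows: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray) -> np.ndarray:
    """r^2 for site pairs (columns of a haplotype matrix), vectorized."""
    p = rows.mean(axis=0)
    pab = (rows[:, idx_i] * rows[:, idx_j]).mean(axis=0)
    num = (pab - p[idx_i] * p[idx_j]) ** 2
    den = p[idx_i] * (1 - p[idx_i]) * p[idx_j] * (1 - p[idx_j])
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def pairwise_r2(panel: HaplotypePanel, site_i: int, site_j: int, group: dict | None = None) -> float:
    """r^2 between two site indices of the panel (both must be segregating)."""
    rows = panel.haplotype_rows(group, np.array([site_i, site_j]))
    p = rows.mean(axis=0)
    if (p == 0).any() or (p == 1).any():
        raise UndefinedStatistic("monomorphic site in r^2")
    out = r2_matrix_pairs(rows, np.array([0]), np.array([1]))
    return float(out[0])


def ld_pairs(
    panel: HaplotypePanel,
    scaffold: str,
    group: dict | None = None,
    max_dist: int = 20_000,
    start: int | None = None,
    end: int | None = None,
    max_pairs: int | None = 500_000,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Distances and r^2 for all segregating-site pairs within ``max_dist``."""
    sites = panel.site_selector(scaffold, start, end)
    rows = panel.haplotype_rows(group, sites)
    pos = panel.sites.loc[sites, "position"].to_numpy()
    p = rows.mean(axis=0)
    seg = (p > 0) & (p < 1)
    rows, pos = rows[:, seg], pos[seg]
    hi = np.searchsorted(pos, pos + max_dist)
    ii = [np.full(hi[i] - i - 1, i) for i in range(len(pos)) if hi[i] > i + 1]
    jj = [np.arange(i + 1, hi[i]) for i in range(len(pos)) if hi[i] > i + 1]
    if not ii:
        return np.array([]), np.array([])
    idx_i, idx_j = np.concatenate(ii), np.concatenate(jj)
    if max_pairs is not None and len(idx_i) > max_pairs:
        if rng is None:
            rng = np.random.default_rng(0)
        sel = rng.choice(len(idx_i), max_pairs, replace=False)
        idx_i, idx_j = idx_i[sel], idx_j[sel]
    d = (pos[idx_j] - pos[idx_i]).astype(float)
    return d, r2_matrix_pairs(rows, idx_i, idx_j)


@dataclass
class LDFit:
    """Fitted LD decay E(r^2) = 1/(1 + alpha d)."""

    alpha: float
    n_pairs: int
    mean_r2: float
    d01: float  # distance at which the fitted curve reaches r^2 = 0.1
    at_boundary: bool = False  # alpha pinned at 0: no measurable decay
    window: tuple | None = field(default=None)


def ld_decay_distance(alpha: float, r2: float = 0.1) -> float:
    """Distance d at which 1/(1 + alpha d) = r2; 9/alpha for r2 = 0.1."""
    if alpha <= 0:
        return float("inf")
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    return (1.0 / r2 - 1.0) / alpha


def ld_decay_fit(
    distances: np.ndarray,
    r2: np.ndarray,
    n_haplotypes: int | None = None,
    window: tuple | None = None,
) -> LDFit:
    """Least-squares fit of alpha >= 0 in E(r^2) = 1/(1 + alpha d).

    With ``n_haplotypes`` given, the model becomes
    ``(1 - f)/(1 + alpha d) + f`` with ``f = 1/(n_haplotypes - 1)``, the
    linkage-equilibrium expectation of sample r^2 — without it, distant pairs
    sit on a noise floor the pure curve cannot reach and alpha is biased
    toward zero on finite samples.  Pass nothing for noiseless curves.
    """
    d = np.asarray(distances, dtype=float)
    y = np.asarray(r2, dtype=float)
    keep = np.isfinite(d) & np.isfinite(y)
    d, y = d[keep], y[keep]
    if len(d) < 10:
        raise UndefinedStatistic("need at least 10 r^2 pairs to fit decay")
    floor = 0.0 if n_haplotypes is None else 1.0 / (n_haplotypes - 1)

    def sse(a: float) -> float:
        return float(np.sum((y - ((1.0 - floor) / (1.0 + a * d) + floor)) ** 2))

    res = minimize_scalar(sse, bounds=(0.0, 10.0), method="bounded", options={"xatol": 1e-12})
    alpha = float(res.x)
    if sse(0.0) <= res.fun:
        alpha = 0.0
    at_boundary = alpha < 1e-9
    return LDFit(
        alpha=alpha,
        n_pairs=len(d),
        mean_r2=float(y.mean()),
        d01=ld_decay_distance(alpha) if not at_boundary else float("inf"),
        at_boundary=at_boundary,
        window=window,
    )


# --------------------------------------------------------------------------
# windowed scan
# --------------------------------------------------------------------------

WINDOW_SIZES_DEFAULT = (20_000, 630_000)


def window_scan(
    panel: HaplotypePanel,
    scaffold_lengths: dict[str, int],
    window_sizes: tuple[int, ...] = WINDOW_SIZES_DEFAULT,
    focal_group: dict | None = None,
    species_pair: tuple[dict, dict] | None = None,
    sex_pair: tuple[dict, dict] | None = None,
    exclude: pd.DataFrame | None = None,
    ld_max_dist: int = 20_000,
    n_haplotypes_for_ld: int | None = None,
) -> pd.DataFrame:
    """Per-window pi / FST / d_f / mean r^2 table over the panel's scaffolds.

    ``exclude`` is an optional BED-like frame (scaffold, start, end; 0-based
    half-open) of sites to drop — e.g. coding intervals when only noncoding
    diversity is wanted; excluded span is also removed from callable length.
    Windows with no usable data carry NaN, never fabricated zeros.
    """
    records = []
    covered = set(panel.sites["scaffold"])
    for size in window_sizes:
        for scaffold, length in scaffold_lengths.items():
            if scaffold not in covered:
                # scaffold absent from the panel: no data, not zero diversity
                for start in range(0, length, size):
                    records.append(
                        {
                            "scaffold": scaffold,
                            "start": start,
                            "end": min(start + size, length),
                            "window_size": size,
                            "callable_sites": 0,
                            "n_sites": 0,
                            "pi": np.nan,
                            "mean_r2": np.nan,
                            "ld_alpha": np.nan,
                        }
                    )
                continue
            for start in range(0, length, size):
                end = min(start + size, length)
                callable_len = end - start
                site_sel = panel.site_selector(scaffold, start, end)
                if exclude is not None:
                    site_sel, callable_len = _apply_exclusions(
                        panel, exclude, scaffold, start, end, site_sel, callable_len
                    )
                rec = {
                    "scaffold": scaffold,
                    "start": start,
                    "end": end,
                    "window_size": size,
                    "callable_sites": callable_len,
                    "n_sites": int(site_sel.sum()),
                }
                rec["pi"] = _maybe(_pi_from_sites, panel, focal_group, site_sel, callable_len)
                if species_pair is not None:
                    rec["fst_species"] = _maybe(
                        lambda *a: weir_cockerham_fst(panel, species_pair[0], species_pair[1], site_sel)
                    )
                    rec["df"] = _maybe(
                        fixed_difference_density,
                        panel, species_pair[0], species_pair[1], scaffold, start, end, callable_len,
                    )
                if sex_pair is not None:
                    rec["fst_sex"] = _maybe(
                        lambda *a: weir_cockerham_fst(panel, sex_pair[0], sex_pair[1], site_sel)
                    )
                rec["mean_r2"], rec["ld_alpha"] = _window_ld(
                    panel, scaffold, focal_group, start, end, ld_max_dist, n_haplotypes_for_ld
                )
                records.append(rec)
    return pd.DataFrame.from_records(records)


def _maybe(func, *args):
    try:
        return func(*args)
    except (UndefinedStatistic, KeyError):
        return np.nan


def _window_ld(panel, scaffold, group, start, end, max_dist, n_hap):
    try:
        d, r2 = ld_pairs(panel, scaffold, group, max_dist, start, end)
        if len(d) < 10:
            return (float(np.nanmean(r2)) if len(d) else np.nan), np.nan
        fit = ld_decay_fit(d, r2, n_haplotypes=n_hap, window=(scaffold, start, end))
        return fit.mean_r2, fit.alpha
    except (UndefinedStatistic, ValueError):
        return np.nan, np.nan


def _apply_exclusions(panel, exclude, scaffold, start, end, site_sel, callable_len):
    sub = exclude[exclude["scaffold"] == scaffold]
    pos0 = panel.sites["position"].to_numpy() - 1
    removed = 0
    sel = site_sel.copy()
    for _, row in sub.iterrows():
        s, e = max(int(row["start"]), start), min(int(row["end"]), end)
        if e > s:
            removed += e - s
            sel &= ~((pos0 >= s) & (pos0 < e) & (panel.sites["scaffold"] == scaffold).to_numpy())
    return sel, max(callable_len - removed, 0)
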