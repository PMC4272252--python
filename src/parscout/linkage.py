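"""Two-point linkage, sex-specific genetic maps, and PAR boundary detection.

The machinery is a simplified pedigree linkage analysis: transmitted parental
alleles are resolved per trio, informative meioses are collected per parent
for each marker pair, and the recombination fraction theta is estimated by
maximizing the meiosis likelihood — phase-known meioses counted directly,
phase-unknown parents summed over their two possible phases with equal
prior.  LOD = log10 L(theta_hat) - log10 L(0.5).

ZW bookkeeping: females carry a single Z, so a dam is never heterozygous at
a differentiated-Z marker.  Her meioses still inform linkage between a PAR
marker and the differentiated region, because which PAR allele rides on the
transmitted Z (to sons) versus the W (to daughters) reveals the crossover;
the differentiated tail acts as a phase-unknown second locus whose
transmission is read off the offspring's sex.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2 as chi2_dist

from ._util import parse_marker_id
from .sim.genotypes import GenotypeTable
from .sim.pedigree import Pedigree

ROLE_Z_DIFF = "Z_diff"

# transmitted-allele sentinel codes
UNKNOWN = -9  # ambiguous or parent genotype missing
ERROR = -8  # impossible given parents
NOT_TRANSMITTED = -1  # e.g. maternal Z_diff slot of a daughter (she got the W)


class InputError(ValueError):
    pass


# --------------------------------------------------------------------------
# genotype encoding and transmitted-allele resolution
# --------------------------------------------------------------------------


def _encode_calls(gt: GenotypeTable) -> tuple[np.ndarray, list[str]]:
    """(n_markers, n_individuals, 2) int8 allele codes; -1 = absent slot.

    Raises nothing on >2 alleles: extra characters get codes >= 2 and are
    screened by the candidate filter.
    """
    alphabet = sorted({c for col in gt.calls.columns for v in gt.calls[col] for c in str(v) if c not in "./"})
    code = {c: i for i, c in enumerate(alphabet)}
    n_m, n_i = gt.calls.shape
    enc = np.full((n_m, n_i, 2), -1, dtype=np.int8)
    values = gt.calls.to_numpy()
    for mi in range(n_m):
        for ii in range(n_i):
            v = str(values[mi, ii])
            if v in (".", "nan", ""):
                continue
            enc[mi, ii, 0] = code[v[0]]
            if len(v) > 1:
                enc[mi, ii, 1] = code[v[1]]
    return enc, alphabet


@dataclass
class TransmissionSet:
    """Resolved transmitted alleles for every trio and marker.

    ``paternal``/``maternal``: (n_trios, n_markers) arrays of allele codes or
    sentinels.  ``trios`` aligns rows with pedigree trios (child, sire, dam,
    sex).  Maternal entries are NOT_TRANSMITTED where the child received the
    W instead of the maternal Z (daughters at differentiated-Z markers).
    """

    trios: pd.DataFrame
    paternal: np.ndarray
    maternal: np.ndarray
    markers: pd.DataFrame
    encoded: np.ndarray
    individual_index: dict[str, int]

    def marker_index(self, marker: str) -> int:
        idx = self.markers.index[self.markers["marker"] == marker]
        if len(idx) == 0:
            raise InputError(f"unknown marker {marker!r}")
        return int(idx[0])


def resolve_transmissions(gt: GenotypeTable, ped: Pedigree) -> TransmissionSet:
    """Determine, per trio and marker, which allele each parent transmitted."""
    enc, _ = _encode_calls(gt)
    trios = ped.trios().reset_index(drop=True)
    ind_index = {ind: i for i, ind in enumerate(gt.calls.columns)}
    n_t, n_m = len(trios), len(gt.markers)
    pat = np.full((n_t, n_m), UNKNOWN, dtype=np.int8)
    mat = np.full((n_t, n_m), UNKNOWN, dtype=np.int8)
    roles = gt.markers["role"].to_numpy()

    ci = np.array([ind_index.get(c, -1) for c in trios["child"]])
    si = np.array([ind_index.get(s, -1) for s in trios["sire"]])
    di = np.array([ind_index.get(d, -1) for d in trios["dam"]])
    sexes = trios["sex"].to_numpy()
    present = (ci >= 0) & (si >= 0) & (di >= 0)

    for mi in range(n_m):
        c0, c1 = enc[mi, ci, 0], enc[mi, ci, 1]
        f0, f1 = enc[mi, si, 0], enc[mi, si, 1]
        m0, m1 = enc[mi, di, 0], enc[mi, di, 1]
        z_diff = roles[mi] == ROLE_Z_DIFF

        def in_f(x):
            return (x >= 0) & (f0 >= 0) & ((x == f0) | (x == f1))

        def in_m(x):
            return (x >= 0) & (m0 >= 0) & ((x == m0) | (x == m1))

        usable = present & (c0 >= 0) & (f0 >= 0) & (m0 >= 0)
        haploid_child = usable & (c1 < 0)
        diploid_child = usable & (c1 >= 0)

        # haploid child (daughter at a differentiated-Z marker): allele is paternal
        ok = haploid_child & in_f(c0)
        pat[ok, mi] = c0[ok]
        mat[ok, mi] = NOT_TRANSMITTED
        bad = haploid_child & ~in_f(c0)
        pat[bad, mi] = ERROR
        mat[bad, mi] = NOT_TRANSMITTED

        if z_diff:
            # a daughter carries one Z: two distinct alleles are impossible
            het_daughter = diploid_child & (sexes == "F") & (c0 != c1)
            pat[het_daughter, mi] = ERROR
            mat[het_daughter, mi] = NOT_TRANSMITTED
            # homozygous diploid call for a daughter: treat as hemizygous
            hom_daughter = diploid_child & (sexes == "F") & (c0 == c1)
            ok = hom_daughter & in_f(c0)
            pat[ok, mi] = c0[ok]
            mat[ok, mi] = NOT_TRANSMITTED
            bad = hom_daughter & ~in_f(c0)
            pat[bad, mi] = ERROR
            mat[bad, mi] = NOT_TRANSMITTED
            diploid_child = diploid_child & (sexes == "M")

        v1 = diploid_child & in_f(c0) & in_m(c1)
        v2 = diploid_child & in_f(c1) & in_m(c0)
        same = diploid_child & (c0 == c1)
        both = v1 & v2 & ~same
        only1 = v1 & ~v2
        only2 = v2 & ~v1
        neither = diploid_child & ~v1 & ~v2
        pat[only1 | (same & v1), mi] = c0[only1 | (same & v1)]
        mat[only1 | (same & v1), mi] = c1[only1 | (same & v1)]
        pat[only2, mi] = c1[only2]
        mat[only2, mi] = c0[only2]
        pat[neither, mi] = ERROR
        mat[neither, mi] = ERROR
        # `both` stays UNKNOWN: transmission ambiguous
    return TransmissionSet(trios, pat, mat, gt.markers, enc, ind_index)


def mendelian_check(gt: GenotypeTable, ped: Pedigree) -> pd.DataFrame:
    """Per-marker count of trios whose genotypes are impossible given the parents."""
    ts = resolve_transmissions(gt, ped)
    errors = ((ts.paternal == ERROR) | (ts.maternal == ERROR)).sum(axis=0)
    out = ts.markers[["marker", "scaffold", "position", "role"]].copy()
    out["mendel_errors"] = errors
    out["n_trios"] = len(ts.trios)
    return out


# --------------------------------------------------------------------------
# Hardy-Weinberg
# --------------------------------------------------------------------------


@dataclass
class HWEResult:
    chi2: float
    p_value: float
    monomorphic: bool
    n: int


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> HWEResult:
    """Pearson chi-square (1 df) against p^2 : 2pq : q^2 expectations."""
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise InputError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise InputError("no genotypes")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return HWEResult(chi2=float("nan"), p_value=float("nan"), monomorphic=True, n=n)
    q = 1 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return HWEResult(chi2=stat, p_value=float(chi2_dist.sf(stat, 1)), monomorphic=False, n=n)


# --------------------------------------------------------------------------
# candidate filter
# --------------------------------------------------------------------------


def filter_candidate_pseudoautosomal(
    gt: GenotypeTable,
    ped: Pedigree | None = None,
    hwe_alpha: float = 0.001,
    max_mendel_errors: int = 0,
    sex_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Screen markers for the pseudoautosomal signature.

    Retained markers have at least one heterozygote and one homozygote in
    males AND in females, pass the Hardy-Weinberg chi-square at ``hwe_alpha``
    (computed on diploid calls), and — when a pedigree is supplied — show at
    most ``max_mendel_errors`` Mendelian inconsistencies.  A hemizygous or
    all-homozygous female pattern (the differentiated-Z signature) fails the
    female-heterozygote requirement.  Returns a per-marker frame with
    ``retained`` and ``reason``.
    """
    if sex_of is None:
        if ped is None:
            raise InputError("need a pedigree or an explicit sex map")
        sex_of = dict(zip(ped.table["id"], ped.table["sex"]))
    mendel = None
    if ped is not None:
        mendel = mendelian_check(gt, ped).set_index("marker")["mendel_errors"]

    male_cols = [c for c in gt.calls.columns if sex_of.get(c) == "M"]
    female_cols = [c for c in gt.calls.columns if sex_of.get(c) == "F"]
    rows = []
    for marker, calls in gt.calls.iterrows():
        reason = ""
        alleles = {ch for v in calls for ch in str(v) if ch not in "./" and str(v) != "nan"}
        if len(alleles) > 2:
            reason = "multiallelic"
        else:
            for cols, label in ((male_cols, "males"), (female_cols, "females")):
                vals = [str(calls[c]) for c in cols]
                het = any(len(v) == 2 and v[0] != v[1] for v in vals)
                hom = any(len(v) == 1 or (len(v) == 2 and v[0] == v[1]) for v in vals)
                if not het:
                    reason = f"no_heterozygote_{label}"
                    break
                if not hom:
                    reason = f"no_homozygote_{label}"
                    break
        if not reason and len(alleles) == 2:
            a, b = sorted(alleles)
            diploid = [str(v) for v in calls if len(str(v)) == 2 and str(v) != "nan"]
            counts = (
                sum(v == a + a for v in diploid),
                sum(v in (a + b, b + a) for v in diploid),
                sum(v == b + b for v in diploid),
            )
            res = hwe_test(*counts)
            if not res.monomorphic and res.p_value < hwe_alpha:
                reason = "hwe_fail"
        if not reason and mendel is not None and mendel.get(marker, 0) > max_mendel_errors:
            reason = "mendel_fail"
        rows.append({"marker": marker, "retained": reason == "", "reason": reason or "pass"})
    return pd.DataFrame(rows)


def candidate_markers(gt: GenotypeTable, ped: Pedigree | None = None, **kwargs) -> list[str]:
    table = filter_candidate_pseudoautosomal(gt, ped, **kwargs)
    return table.loc[table["retained"], "marker"].tolist()


# --------------------------------------------------------------------------
# two-point likelihood
# --------------------------------------------------------------------------


@dataclass
class TwoPointResult:
    marker_a: str
    marker_b: str
    theta_sexavg: float
    theta_female: float
    theta_male: float
    lod_sexavg: float
    lod_female: float
    lod_male: float
    n_informative_f: int
    n_informative_m: int


@dataclass
class _ParentFamily:
    """One parent's informative meioses for a marker pair.

    ``r`` counts offspring recombinant under an arbitrary phase labelling,
    out of ``n``; with known phase the labelling is the true one.
    """

    r: int
    n: int
    phase_known: bool

    def loglik(self, theta: float) -> float:
        t = min(max(theta, 1e-12), 0.5)
        lk = self.r * math.log(t) + (self.n - self.r) * math.log(1 - t)
        if self.phase_known:
            return lk
        flip = (self.n - self.r) * math.log(t) + self.r * math.log(1 - t)
        m = max(lk, flip)
        return m + math.log(0.5 * (math.exp(lk - m) + math.exp(flip - m)))


def _phase_from_grandparents(ts: TransmissionSet, parent: str, ia: int, ib: int) -> bool | None:
    """True/False = known phase orientation (True: allele0@a cis allele0@b); None unknown.

    Uses the parent's own row in the trio table: if the grandpaternal origin
    of the parent's alleles is resolved at both markers, phase is read off.
    """
    rows = ts.trios.index[ts.trios["child"] == parent]
    if len(rows) == 0:
        return None
    row = rows[0]
    pa, ma = ts.paternal[row, ia], ts.maternal[row, ia]
    pb, mb = ts.paternal[row, ib], ts.maternal[row, ib]
    if min(pa, ma, pb, mb) < 0:  # unresolved or not biparentally transmitted
        return None
    enc = ts.encoded
    pi = ts.individual_index[parent]
    a0 = enc[ia, pi, 0]
    b0 = enc[ib, pi, 0]
    # grandpaternal haplotype carries (pa, pb): phase True iff a0 and b0 co-reside
    return (pa == a0) == (pb == b0)


def _collect_families(
    ts: TransmissionSet, ia: int, ib: int, parent_sex: str
) -> list[_ParentFamily]:
    trios = ts.trios
    parent_col = "sire" if parent_sex == "M" else "dam"
    trans = ts.paternal if parent_sex == "M" else ts.maternal
    enc = ts.encoded
    roles = ts.markers["role"].to_numpy()
    families = []
    for parent, group in trios.groupby(parent_col, sort=True):
        pi = ts.individual_index.get(parent)
        if pi is None:
            continue
        ga = enc[ia, pi]
        gb = enc[ib, pi]
        rows = group.index.to_numpy()
        het_a = ga[0] >= 0 and ga[1] >= 0 and ga[0] != ga[1]
        het_b = gb[0] >= 0 and gb[1] >= 0 and gb[0] != gb[1]
        hemi_b = parent_sex == "F" and roles[ib] == ROLE_Z_DIFF and gb[0] >= 0 and gb[1] < 0
        hemi_a = parent_sex == "F" and roles[ia] == ROLE_Z_DIFF and ga[0] >= 0 and ga[1] < 0
        if het_a and het_b:
            ta, tb = trans[rows, ia], trans[rows, ib]
            ok = (ta >= 0) & (tb >= 0)
            n = int(ok.sum())
            if n == 0:
                continue
            r = int(((ta[ok] == ga[0]) != (tb[ok] == gb[0])).sum())
            phase = _phase_from_grandparents(ts, parent, ia, ib)
            if phase is None:
                families.append(_ParentFamily(r=r, n=n, phase_known=False))
            else:
                families.append(_ParentFamily(r=r if phase else n - r, n=n, phase_known=True))
        elif het_a and hemi_b:
            families.append(_hemizygous_family(ts, trans, rows, ia, ga))
        elif het_b and hemi_a:
            families.append(_hemizygous_family(ts, trans, rows, ib, gb))
    return [f for f in families if f is not None and f.n > 0]


def _hemizygous_family(ts, trans, rows, i_het, g_het) -> _ParentFamily | None:
    """Dam heterozygous at a PAR marker, hemizygous at the differentiated one.

    The second 'locus' is the identity of the transmitted tail (Z to sons, W
    to daughters), read off offspring sex; which PAR allele rides the Z is
    unknown, so the family is phase-unknown.
    """
    ta = trans[rows, i_het]
    sexes = ts.trios.loc[rows, "sex"].to_numpy()
    ok = ta >= 0
    n = int(ok.sum())
    if n == 0:
        return None
    r = int(((ta[ok] == g_het[0]) != (sexes[ok] == "M")).sum())
    return _ParentFamily(r=r, n=n, phase_known=False)


def _maximize(families: list[_ParentFamily]) -> tuple[float, float]:
    """(theta_hat, LOD) for a set of parent families; (nan, 0) if none."""
    if not families:
        return float("nan"), 0.0
    if all(f.phase_known for f in families):
        r = sum(f.r for f in families)
        n = sum(f.n for f in families)
        theta = min(r / n, 0.5)
    else:
        res = minimize_scalar(
            lambda t: -sum(f.loglik(t) for f in families),
            bounds=(0.0, 0.5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        theta = float(res.x)
        # the boundary can beat the interior optimum found numerically
        for cand in (0.0, 0.5):
            if sum(f.loglik(cand) for f in families) > sum(f.loglik(theta) for f in families):
                theta = cand
    ll_hat = sum(f.loglik(theta) for f in families)
    ll_null = sum(f.loglik(0.5) for f in families)
    lod = max((ll_hat - ll_null) / math.log(10), 0.0)
    return theta, lod


def twopoint(gt: GenotypeTable, ped: Pedigree, marker_a: str, marker_b: str,
             ts: TransmissionSet | None = None) -> TwoPointResult:
    """Sex-specific and pooled two-point linkage between two markers."""
    if ts is None:
        ts = resolve_transmissions(gt, ped)
    ia, ib = ts.marker_index(marker_a), ts.marker_index(marker_b)
    fam_f = _collect_families(ts, ia, ib, "F")
    fam_m = _collect_families(ts, ia, ib, "M")
    theta_f, lod_f = _maximize(fam_f)
    theta_m, lod_m = _maximize(fam_m)
    theta_s, lod_s = _maximize(fam_f + fam_m)
    return TwoPointResult(
        marker_a=marker_a,
        marker_b=marker_b,
        theta_sexavg=theta_s,
        theta_female=theta_f,
        theta_male=theta_m,
        lod_sexavg=lod_s,
        lod_female=lod_f,
        lod_male=lod_m,
        n_informative_f=sum(f.n for f in fam_f),
        n_informative_m=sum(f.n for f in fam_m),
    )


def assign_by_lod(
    gt: GenotypeTable,
    ped: Pedigree,
    candidates: list[str],
    anchors: list[str],
    threshold: float = 3.0,
    ts: TransmissionSet | None = None,
) -> pd.DataFrame:
    """Assign candidates to the anchor linkage group by max pairwise LOD."""
    if ts is None:
        ts = resolve_transmissions(gt, ped)
    rows = []
    for cand in candidates:
        best_lod, best_anchor, best_theta = 0.0, None, float("nan")
        for anchor in anchors:
            res = twopoint(gt, ped, cand, anchor, ts=ts)
            if res.lod_sexavg > best_lod:
                best_lod, best_anchor, best_theta = res.lod_sexavg, anchor, res.theta_sexavg
        rows.append(
            {
                "marker": cand,
                "best_anchor": best_anchor,
                "best_lod": best_lod,
                "theta": best_theta,
                "assigned": best_lod > threshold,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# map construction
# --------------------------------------------------------------------------

MAP_FUNCTIONS = ("haldane", "kosambi")


def map_distance_cm(theta: float, map_function: str = "haldane") -> float:
    """Map-function transform of a recombination fraction, in cM."""
    if math.isnan(theta):
        return 0.0
    # distances beyond theta ~ 0.499 (> 300 cM for one interval) are not
    # resolvable from a single interval; cap to keep sparse-data maps finite
    t = min(max(theta, 0.0), 0.499)
    if map_function == "haldane":
        return -50.0 * math.log(1.0 - 2.0 * t)
    if map_function == "kosambi":
        return 25.0 * math.log((1.0 + 2.0 * t) / (1.0 - 2.0 * t))
    raise ValueError(f"unknown map function {map_function!r}")


@dataclass
class GeneticMap:
    """Ordered markers with sex-averaged / female / male cumulative positions.

    ``table`` columns: marker, scaffold, position, cum_sexavg, cum_female,
    cum_male, theta_f, theta_m, theta_sexavg (interval to the next marker;
    NaN for the last marker and for uninformative intervals, which advance
    the map by 0 cM).
    """

    table: pd.DataFrame
    map_function: str = "haldane"

    def __post_init__(self) -> None:
        for col in ("cum_sexavg", "cum_female", "cum_male"):
            c = self.table[col].to_numpy()
            if len(c) and (np.diff(c) < -1e-9).any():
                raise ValueError(f"{col} must be non-decreasing")

    @classmethod
    def from_positions(cls, table: pd.DataFrame, map_function: str = "haldane") -> "GeneticMap":
        t = table.copy()
        for col in ("theta_f", "theta_m", "theta_sexavg"):
            if col not in t.columns:
                t[col] = np.nan
        if "scaffold" not in t.columns:
            parsed = [parse_marker_id(m) for m in t["marker"]]
            t["scaffold"] = [p[0] for p in parsed]
            t["position"] = [p[1] for p in parsed]
        return cls(t.reset_index(drop=True), map_function)

    def female_length(self) -> float:
        return float(self.table["cum_female"].iloc[-1] - self.table["cum_female"].iloc[0])

    def male_length(self) -> float:
        return float(self.table["cum_male"].iloc[-1] - self.table["cum_male"].iloc[0])


def build_map(
    gt: GenotypeTable,
    ped: Pedigree,
    order: list[str],
    map_function: str = "haldane",
    ts: TransmissionSet | None = None,
) -> GeneticMap:
    """Sex-specific map over a fixed marker order via adjacent two-point."""
    if map_function not in MAP_FUNCTIONS:
        raise ValueError(f"map function must be one of {MAP_FUNCTIONS}")
    if ts is None:
        ts = resolve_transmissions(gt, ped)
    known = set(gt.markers["marker"])
    for m in order:
        if m not in known:
            raise InputError(f"order contains unknown marker {m!r}")
    meta = gt.markers.set_index("marker")
    rows = []
    cum = {"f": 0.0, "m": 0.0, "s": 0.0}
    for i, marker in enumerate(order):
        rec = {
            "marker": marker,
            "scaffold": meta.at[marker, "scaffold"],
            "position": int(meta.at[marker, "position"]),
            "cum_sexavg": cum["s"],
            "cum_female": cum["f"],
            "cum_male": cum["m"],
            "theta_f": np.nan,
            "theta_m": np.nan,
            "theta_sexavg": np.nan,
        }
        if i < len(order) - 1:
            tp = twopoint(gt, ped, marker, order[i + 1], ts=ts)
            rec["theta_f"], rec["theta_m"] = tp.theta_female, tp.theta_male
            rec["theta_sexavg"] = tp.theta_sexavg
            cum["f"] += map_distance_cm(tp.theta_female, map_function) if not math.isnan(tp.theta_female) else 0.0
            cum["m"] += map_distance_cm(tp.theta_male, map_function) if not math.isnan(tp.theta_male) else 0.0
            cum["s"] += map_distance_cm(tp.theta_sexavg, map_function) if not math.isnan(tp.theta_sexavg) else 0.0
        rows.append(rec)
    return GeneticMap(pd.DataFrame(rows), map_function)


def best_order(
    gt: GenotypeTable,
    ped: Pedigree,
    markers: list[str],
    map_function: str = "haldane",
    ts: TransmissionSet | None = None,
) -> list[str]:
    """Exhaustive order search (<= 10 markers) minimizing total adjacent theta.

    Ties break lexicographically on the marker id sequence; an order and its
    reverse are equivalent and the lexicographically smaller one is returned.
    """
    if len(markers) > 10:
        raise InputError("exhaustive order search is limited to 10 markers")
    if ts is None:
        ts = resolve_transmissions(gt, ped)
    theta_cache: dict[tuple[str, str], float] = {}

    def theta(a: str, b: str) -> float:
        key = (min(a, b), max(a, b))
        if key not in theta_cache:
            t = twopoint(gt, ped, key[0], key[1], ts=ts).theta_sexavg
            theta_cache[key] = 0.5 if math.isnan(t) else t
        return theta_cache[key]

    best: tuple[float, tuple[str, ...]] | None = None
    for perm in itertools.permutations(sorted(markers)):
        if perm[0] > perm[-1]:  # canonical direction only
            continue
        cost = sum(theta(perm[i], perm[i + 1]) for i in range(len(perm) - 1))
        key = (cost, perm)
        if best is None or key < best:
            best = key
    return list(best[1])


# --------------------------------------------------------------------------
# rates, hotspots, boundary
# --------------------------------------------------------------------------


@dataclass
class IntervalRate:
    left: str
    right: str
    genetic_length: float  # cM
    physical_length: int  # bp, padded across scaffold gaps
    sex: str

    @property
    def rate(self) -> float:
        if self.physical_length <= 0:
            return float("nan")
        return self.genetic_length / (self.physical_length * 1e-6)


def physical_distance(
    marker_a: str,
    marker_b: str,
    scaffold_lengths: dict[str, int],
    scaffold_order: list[str],
    gap_padding: int = 5_000,
) -> int:
    """bp between two markers, crossing scaffold gaps with padding per gap."""
    scaf_a, pos_a = parse_marker_id(marker_a)
    scaf_b, pos_b = parse_marker_id(marker_b)
    if scaf_a == scaf_b:
        return abs(pos_b - pos_a)
    order = {s: i for i, s in enumerate(scaffold_order)}
    ia, ib = order[scaf_a], order[scaf_b]
    if ia > ib:
        (scaf_a, pos_a, ia), (scaf_b, pos_b, ib) = (scaf_b, pos_b, ib), (scaf_a, pos_a, ia)
    dist = scaffold_lengths[scaf_a] - pos_a + gap_padding + pos_b
    for mid in scaffold_order[ia + 1 : ib]:
        dist += scaffold_lengths[mid] + gap_padding
    return dist


def region_physical_length(scaffold_lengths_bp: list[int], gap_padding: int = 5_000) -> int:
    """Total span of consecutive scaffolds with padding added per inter-scaffold gap."""
    return int(sum(scaffold_lengths_bp) + gap_padding * (len(scaffold_lengths_bp) - 1))


def interval_rates(
    gmap: GeneticMap,
    scaffold_lengths: dict[str, int],
    scaffold_order: list[str] | None = None,
    gap_padding: int = 5_000,
    sex: str = "female",
) -> pd.DataFrame:
    """cM/Mb for each adjacent interval of the map, for one sex or sex-averaged."""
    col = {"female": "cum_female", "male": "cum_male", "sexavg": "cum_sexavg"}[sex]
    if scaffold_order is None:
        scaffold_order = list(dict.fromkeys(gmap.table["scaffold"]))
    t = gmap.table
    rows = []
    for i in range(len(t) - 1):
        left, right = t.iloc[i], t.iloc[i + 1]
        phys = physical_distance(
            left["marker"], right["marker"], scaffold_lengths, scaffold_order, gap_padding
        )
        genetic = float(right[col] - left[col])
        rows.append(
            {
                "left": left["marker"],
                "right": right["marker"],
                "genetic_length_cm": genetic,
                "physical_length_bp": phys,
                "rate_cm_per_mb": genetic / (phys * 1e-6) if phys > 0 else np.nan,
                "sex": sex,
            }
        )
    return pd.DataFrame(rows)


def pair_rate(
    gmap: GeneticMap,
    marker_a: str,
    marker_b: str,
    scaffold_lengths: dict[str, int],
    scaffold_order: list[str] | None = None,
    gap_padding: int = 5_000,
    sex: str = "female",
) -> IntervalRate:
    """cM/Mb between two (not necessarily adjacent) markers of a map."""
    col = {"female": "cum_female", "male": "cum_male", "sexavg": "cum_sexavg"}[sex]
    t = gmap.table.set_index("marker")
    if scaffold_order is None:
        scaffold_order = list(dict.fromkeys(gmap.table["scaffold"]))
    genetic = abs(float(t.at[marker_b, col] - t.at[marker_a, col]))
    phys = physical_distance(marker_a, marker_b, scaffold_lengths, scaffold_order, gap_padding)
    return IntervalRate(left=marker_a, right=marker_b, genetic_length=genetic,
                        physical_length=phys, sex=sex)


def detect_hotspots(rates: pd.DataFrame, fold: float = 10.0) -> pd.DataFrame:
    """Flag intervals whose rate exceeds ``fold`` times the mean interval rate."""
    if len(rates) < 2:
        raise InputError("need at least two intervals")
    out = rates.copy()
    mean_rate = out["rate_cm_per_mb"].mean(skipna=True)
    out["hotspot"] = out["rate_cm_per_mb"] > fold * mean_rate
    out["fold_over_mean"] = out["rate_cm_per_mb"] / mean_rate if mean_rate > 0 else np.nan
    return out


@dataclass
class BoundaryResult:
    boundary_marker: str | None  # distal-most marker still recombining in females
    next_marker: str | None  # first marker beyond the boundary
    par_markers: list[str]
    z_diff_markers: list[str]
    female_span_cm: float


def detect_par_boundary(gmap: GeneticMap, tol: float = 1e-9) -> BoundaryResult:
    """Locate where cumulative female cM stops increasing along the map.

    Markers up to and including the boundary marker are PAR-labelled; all
    markers past it are differentiated-Z.  If females never recombine the
    whole region is differentiated (boundary None); if they recombine to the
    end, the boundary is the last marker.
    """
    t = gmap.table
    cum = t["cum_female"].to_numpy()
    increases = np.flatnonzero(np.diff(cum) > tol)
    if len(increases) == 0:
        return BoundaryResult(None, None, [], t["marker"].tolist(), 0.0)
    last = int(increases[-1]) + 1  # index of the distal-most recombining marker
    markers = t["marker"].tolist()
    return BoundaryResult(
        boundary_marker=markers[last],
        next_marker=markers[last + 1] if last + 1 < len(markers) else None,
        par_markers=markers[: last + 1],
        z_diff_markers=markers[last + 1 :],
        female_span_cm=float(cum[last] - cum[0]),
    )
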